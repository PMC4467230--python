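"""End-to-end orchestration: synthesize -> preprocess -> decode -> generalize -> stats.

`run_full_analysis` executes, per replicate: condition-split decoding
curves with window statistics and chance correction, the asymmetric
cross-condition hemifield transfer, temporal generalization matrices
with Classification Endurance (and its ANOVA across replicates),
GFP-guided evoked cluster statistics, and the control analyses
(EOG-only decoding, target-absent response decoding, visibility
decoder).  Every table written carries the generating config hash and
the run is byte-reproducible from config + seeds.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, generalization
from .decoding import assign_folds, decode_timecourse, correct_class_series, chance_corrected_mean
from .epochs import EpochSet, trials_to_tsv
from .evoked import cluster_permutation_test, component_windows, evoked_from_epochs, knn_adjacency
from .preprocess import BaselineSpec, baseline_zscore, select_subset
from .synth import ObserverModel, SignalRecipe, generate_epochs, hemifield_of, simulate_behavior

logger = logging.getLogger("meegdecode")

__all__ = ["RunConfig", "run_full_analysis", "read_config", "config_hash"]


@dataclass
class RunConfig:
    recipe: SignalRecipe = field(default_factory=SignalRecipe)
    observer: ObserverModel = field(default_factory=ObserverModel)
    contrast: float = 131.0
    n_absent: int = 40
    n_replicates: int = 3
    k_folds: int = 15
    k_folds_visibility: int = 10
    baseline_window: tuple[float, float] = (-500.0, 0.0)
    eog_control: bool = True
    absent_control: bool = True
    visibility_decoder: bool = True
    roi_decoding: bool = False
    tgm: bool = True
    evoked_cluster: bool = True
    cluster_n_perm: int = 200
    seed: int = 0

    @property
    def stage_windows(self) -> dict:
        return {f"stage{i+1}": w for i, w in enumerate(self.recipe.stage_windows)}


_KNOWN_KEYS = {
    "recipe": {f.name for f in dataclasses.fields(SignalRecipe)},
    "observer": {f.name for f in dataclasses.fields(ObserverModel)},
    "run": {f.name for f in dataclasses.fields(RunConfig)} - {"recipe", "observer"},
}


def read_config(path) -> RunConfig:
    """Parse the flat sectioned key=value config file; unknown keys are errors."""
    cp = configparser.ConfigParser()
    cp.read(path)
    kwargs: dict = {"recipe": {}, "observer": {}, "run": {}}
    for section in cp.sections():
        if section not in _KNOWN_KEYS:
            raise ValueError(f"unknown config section '{section}'")
        for key, raw in cp[section].items():
            if key not in _KNOWN_KEYS[section]:
                raise ValueError(f"unknown key '{key}' in section [{section}]")
            kwargs[section][key] = json.loads(raw)
    recipe = SignalRecipe(**kwargs["recipe"])
    observer = ObserverModel(**kwargs["observer"])
    run_kwargs = kwargs["run"]
    for tup_key in ("baseline_window",):
        if tup_key in run_kwargs:
            run_kwargs[tup_key] = tuple(run_kwargs[tup_key])
    return RunConfig(recipe=recipe, observer=observer, **run_kwargs)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as f:
        f.write(f"# config={chash}\n")
        df.to_csv(f, sep="\t", index=False, float_format="%.10g")


@contextmanager
def _stage(name: str):
    t0 = time.time()
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    logger.info("stage %s: done in %.1f s", name, time.time() - t0)


def _rep_seed(config: RunConfig, rep: int, stage: int) -> int:
    ss = np.random.SeedSequence(config.seed, spawn_key=(rep, stage))
    return int(ss.generate_state(1)[0] % (2**31))


def run_full_analysis(config: RunConfig, out_dir) -> dict:
    """Run the whole pipeline and write the report bundle under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    chance8 = 1.0 / 8
    summary: dict = {"config_hash": chash, "n_replicates": config.n_replicates, "replicates": []}

    curves_by_cond: dict[str, list[np.ndarray]] = {}
    xfer_series: dict[str, list[np.ndarray]] = {}
    ce_profiles: dict = {}
    evoked_seen, evoked_unseen = [], []
    eog_series: dict[str, list[np.ndarray]] = {}
    absent_curves, vis_curves = [], []
    all_curve_rows, tgm_paths = [], []
    times = None

    for rep in range(config.n_replicates):
        with _stage(f"simulate[rep{rep}]"):
            behavior = simulate_behavior(
                config.observer, config.contrast, config.recipe.n_trials,
                seed=_rep_seed(config, rep, 0), n_absent=config.n_absent,
            )
            recipe = replace(config.recipe, n_trials=len(behavior), seed=_rep_seed(config, rep, 1))
            epochs = generate_epochs(recipe, behavior)
            trials_to_tsv(behavior, out / f"behavior_rep{rep}.tsv")
        with _stage(f"preprocess[rep{rep}]"):
            epochs = baseline_zscore(epochs, BaselineSpec(config.baseline_window))
        times = epochs.times
        tr = epochs.trials
        present = tr["target_present"].to_numpy(dtype=bool)
        seen = tr["seen"].to_numpy(dtype=bool)
        correct = tr["correct"].to_numpy(dtype=bool)
        conds = {
            "all": present,
            "seen_correct": present & seen & correct,
            "unseen_correct": present & ~seen & correct,
            "unseen_incorrect": present & ~seen & ~correct,
        }

        with _stage(f"decode8[rep{rep}]"):
            pres_epochs, imap = select_subset(epochs, trial_filter=present)
            labels = pres_epochs.trials["location"].to_numpy()
            folds = assign_folds(pres_epochs.n_trials, config.k_folds, _rep_seed(config, rep, 2))
            result = decode_timecourse(pres_epochs, labels, folds)
            sub_conds = {name: conds[name][imap["trials"]] for name in conds}
            sub_conds = {k: v for k, v in sub_conds.items() if v.any()}
            curves = correct_class_series(result, labels, sub_conds)
            curves["replicate"] = rep
            all_curve_rows.append(curves)
            for name in sub_conds:
                series = curves[curves["condition"] == name]["mean"].to_numpy()
                curves_by_cond.setdefault(name, []).append(series)
            dist = decoding.distance_profile(result, labels)
            _write_table(
                pd.DataFrame(dist.T, columns=[f"d{d}" for d in range(5)]).assign(time_ms=times),
                out / f"distance_profile_rep{rep}.tsv", chash,
            )
            # blindsight chance correction of the unseen-correct curve
            if sub_conds.get("unseen_correct") is not None and "unseen_incorrect" in sub_conds:
                cc = decoding.correct_probabilities(result, labels)
                uc, ui = sub_conds["unseen_correct"], sub_conds["unseen_incorrect"]
                corrected = chance_corrected_mean(
                    cc[uc].mean(axis=0), cc[ui].mean(axis=0), int(uc.sum()), int(ui.sum())
                )
                curves_by_cond.setdefault("unseen_correct_chance_corrected", []).append(corrected)

        with _stage(f"crosscond[rep{rep}]"):
            tr2 = epochs.trials.assign(hemifield=np.where(present, hemifield_of(tr["location"]), ""))
            ep2 = epochs.copy()
            ep2.trials = tr2
            bal, bmap = select_subset(
                ep2, trial_filter=(present & correct).tolist(),
                balance=["hemifield", "seen"], seed=_rep_seed(config, rep, 3),
            )
            hemi = bal.trials["hemifield"].to_numpy()
            bseen = bal.trials["seen"].to_numpy(dtype=bool)
            for train_name, m_train, m_test in (
                ("train_seen", bseen, ~bseen),
                ("train_unseen", ~bseen, bseen),
            ):
                res = generalization.cross_condition_curves(
                    bal, hemi, m_train, m_test, k=config.k_folds, seed=_rep_seed(config, rep, 4)
                )
                xfer_series.setdefault(f"{train_name}_within", []).append(res.within_curve)
                xfer_series.setdefault(f"{train_name}_transfer", []).append(res.transfer_curve)

        if config.tgm:
            with _stage(f"tgm[rep{rep}]"):
                for vis, mask in (("seen", conds["seen_correct"]), ("unseen", conds["unseen_correct"])):
                    sub, _ = select_subset(epochs, trial_filter=mask.tolist())
                    hlab = hemifield_of(sub.trials["location"].to_numpy())
                    tfolds = assign_folds(sub.n_trials, min(config.k_folds, sub.n_trials),
                                          _rep_seed(config, rep, 5))
                    mat = generalization.temporal_generalization_matrix(
                        sub, hlab, tfolds, keep_trials=False, train_cond=vis, test_cond=vis
                    )
                    _write_table(
                        pd.DataFrame(mat.values, columns=[f"{t:.3f}" for t in times]).assign(train_ms=times),
                        out / f"tgm_{vis}_rep{rep}.tsv", chash,
                    )
                    tgm_paths.append(f"tgm_{vis}_rep{rep}.tsv")
                    ce_profiles[(rep, vis)] = generalization.classification_endurance(mat, 0.5)

        if config.evoked_cluster:
            with _stage(f"evoked[rep{rep}]"):
                evoked_seen.append(evoked_from_epochs(epochs, conds["seen_correct"], "seen_correct"))
                evoked_unseen.append(evoked_from_epochs(epochs, conds["unseen_correct"], "unseen_correct"))

        if config.eog_control:
            with _stage(f"eog_control[rep{rep}]"):
                eog, emap = select_subset(epochs, channel_filter={"type": "eog"}, trial_filter=present)
                elabels = eog.trials["location"].to_numpy()
                efolds = assign_folds(eog.n_trials, config.k_folds, _rep_seed(config, rep, 6))
                eres = decode_timecourse(eog, elabels, efolds)
                emasks = {n: conds[n][emap["trials"]] for n in ("seen_correct", "unseen_correct")}
                ecur = correct_class_series(eres, elabels, emasks)
                for name in emasks:
                    eog_series.setdefault(name, []).append(
                        ecur[ecur["condition"] == name]["mean"].to_numpy()
                    )

        if config.absent_control and (~present).any():
            with _stage(f"absent_control[rep{rep}]"):
                # train on target location in present trials; test on the manual
                # response given on target-absent trials
                mixed_labels = np.where(present, tr["location"], tr["response"]).astype(int)
                res = generalization.cross_condition_curves(
                    epochs, mixed_labels, present, ~present,
                    k=config.k_folds, seed=_rep_seed(config, rep, 7),
                )
                absent_curves.append(res.transfer_curve)

        if config.visibility_decoder:
            with _stage(f"visibility[rep{rep}]"):
                vmask = conds["seen_correct"] | conds["unseen_correct"]
                vbal, _ = select_subset(
                    epochs, trial_filter=vmask.tolist(), balance=["location", "seen"],
                    seed=_rep_seed(config, rep, 8),
                )
                vlabels = np.where(vbal.trials["seen"], "seen", "unseen")
                vfolds = assign_folds(vbal.n_trials, config.k_folds_visibility,
                                      _rep_seed(config, rep, 9))
                vres = decode_timecourse(vbal, vlabels, vfolds)
                vcc = decoding.correct_probabilities(vres, vlabels)
                vis_curves.append(vcc.mean(axis=0))

        summary["replicates"].append({"replicate": rep, "n_trials": int(len(tr))})

    with _stage("aggregate"):
        _write_table(pd.concat(all_curve_rows, ignore_index=True), out / "decoding_curves.tsv", chash)
        stats_series = {c: np.vstack(v) for c, v in curves_by_cond.items()
                        if len(v) == config.n_replicates}
        if config.n_replicates >= 2:
            pairs = []
            if {"seen_correct", "unseen_correct"} <= stats_series.keys():
                pairs.append(("seen_correct", "unseen_correct"))
            if {"seen_correct", "unseen_correct_chance_corrected"} <= stats_series.keys():
                pairs.append(("seen_correct", "unseen_correct_chance_corrected"))
            ws = decoding.window_stats(stats_series, times, config.stage_windows, chance8, pairs)
            _write_table(ws.per_window, out / "window_stats.tsv", chash)
            _write_table(ws.paired, out / "window_stats_paired.tsv", chash)
            summary["stage4_means"] = {
                c: float(np.vstack(v)[:, (times >= 271) & (times < 800)].mean())
                for c, v in stats_series.items()
            }
        xfer_rows = []
        for name, series in xfer_series.items():
            arr = np.vstack(series)
            xfer_rows.append(pd.DataFrame({"series": name, "time_ms": times,
                                           "mean": arr.mean(axis=0)}))
        if xfer_rows:
            _write_table(pd.concat(xfer_rows, ignore_index=True), out / "crosscond_curves.tsv", chash)

        if config.tgm and ce_profiles:
            table = generalization.ce_table(ce_profiles, window=config.recipe.stage_windows[3])
            _write_table(table, out / "ce_table.tsv", chash)
            if config.n_replicates >= 2 and not table["ce_ms"].isna().any():
                res = generalization.ce_anova(table)
                _write_table(res["anova"].reset_index(), out / "ce_anova.tsv", chash)
                _write_table(res["contrasts"], out / "ce_contrasts.tsv", chash)
                summary["ce_forward_ms"] = {
                    vis: float(table[(table.visibility == vis) & (table.direction == "forward")]["ce_ms"].mean())
                    for vis in ("seen", "unseen")
                }

        if config.evoked_cluster and len(evoked_seen) >= 2:
            grand = np.mean([e.data for e in evoked_seen + evoked_unseen], axis=0)
            gfp = np.std(grand, axis=0, ddof=0)
            _write_table(pd.DataFrame({"time_ms": times, "gfp": gfp}), out / "gfp.tsv", chash)
            windows = component_windows(gfp, times)
            _, adj = knn_adjacency(epochs.n_channels, k=4, seed=config.seed)
            cl_rows = []
            for w in windows:
                cres = cluster_permutation_test(
                    evoked_seen, evoked_unseen, w, adj,
                    n_perm=config.cluster_n_perm, seed=_rep_seed(config, 0, 10),
                )
                for c in cres.clusters:
                    cl_rows.append({"window_start_ms": w[0], "window_end_ms": w[1],
                                    "mass": c["mass"], "p": c["p"],
                                    "n_channels": len(c["channels"])})
            _write_table(pd.DataFrame(cl_rows), out / "clusters.tsv", chash)
            summary["cluster_windows_ms"] = [list(map(float, w)) for w in windows]

        if eog_series:
            rows = [pd.DataFrame({"condition": n, "time_ms": times, "mean": np.vstack(v).mean(axis=0)})
                    for n, v in eog_series.items()]
            _write_table(pd.concat(rows, ignore_index=True), out / "eog_curves.tsv", chash)
        if absent_curves:
            _write_table(pd.DataFrame({"time_ms": times, "mean": np.vstack(absent_curves).mean(axis=0)}),
                         out / "absent_control.tsv", chash)
            summary["absent_control_mean"] = float(np.vstack(absent_curves).mean())
        if vis_curves:
            _write_table(pd.DataFrame({"time_ms": times, "mean": np.vstack(vis_curves).mean(axis=0)}),
                         out / "visibility_curve.tsv", chash)

    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True)
    return summary
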