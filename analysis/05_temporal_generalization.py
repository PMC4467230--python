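"""Temporal generalization matrices and Classification Endurance.

Computes train-time x test-time generalization separately for
seen-correct and unseen-correct trials across simulated replicates and
derives forward/backward Classification Endurance (the decoder
half-life on above-chance excess) by both routes: per replicate (for
the Visibility x Direction x Timeframe repeated-measures ANOVA) and on
the replicate-averaged matrix (the low-noise headline numbers — CE's
contiguous-run rule truncates early on noisy single-replicate
matrices).  Expected signature: the single lingering unseen code
generalizes further forward than the chained seen codes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from meegdecode import (
    BaselineSpec,
    GeneralizationMatrix,
    ObserverModel,
    SignalRecipe,
    assign_folds,
    baseline_zscore,
    ce_anova,
    ce_table,
    classification_endurance,
    generate_epochs,
    hemifield_of,
    select_subset,
    simulate_behavior,
    temporal_generalization_matrix,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 5
N_REPLICATES = 6
# late stage widened so the chain runs at the published ~160 ms state duration;
# SNR above the default so the decaying unseen code stays decodable to the end
# (single replicates at the default SNR leave late unseen frames undefined)
STAGE4 = (271.0, 911.0)
STAGES = ((0.0, 115.0), (115.0, 162.0), (162.0, 271.0), STAGE4)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    profiles = {}
    matrices = {"seen": [], "unseen": []}
    times = None
    for rep in range(N_REPLICATES):
        behavior = simulate_behavior(ObserverModel(), 131.0, 240, seed=SEED + 100 * rep)
        recipe = SignalRecipe(n_trials=240, n_channels=20, epoch_window=(-200.0, 950.0),
                              stage_windows=STAGES, state_duration_ms=160.0,
                              pattern_snr=3.0, seed=SEED + 100 * rep + 1)
        epochs = baseline_zscore(generate_epochs(recipe, behavior), BaselineSpec((-200.0, 0.0)))
        tr = epochs.trials
        for vis in ("seen", "unseen"):
            mask = (tr["seen"] == (vis == "seen")) & tr["correct"]
            sub, _ = select_subset(epochs, trial_filter=mask.tolist())
            hemi = hemifield_of(sub.trials["location"].to_numpy())
            folds = assign_folds(sub.n_trials, 8, seed=SEED + 100 * rep + 2)
            mat = temporal_generalization_matrix(sub, hemi, folds, keep_trials=False)
            times = mat.times
            matrices[vis].append(mat.values)
            profiles[(rep, vis)] = classification_endurance(mat, 0.5)

    print("CE on the replicate-averaged matrices, stage-4 mean (ms):")
    m4 = (times >= STAGE4[0]) & (times < STAGE4[1])
    for vis in ("seen", "unseen"):
        avg = GeneralizationMatrix(np.mean(matrices[vis], axis=0), times)
        pd.DataFrame(avg.values, columns=[f"{t:.1f}" for t in times]).to_csv(
            OUT / f"tgm_{vis}.tsv", sep="\t", index=False, float_format="%.4f")
        prof = classification_endurance(avg, 0.5)
        print(f"  {vis:6s} forward {np.nanmean(prof.ce_forward_ms[m4]):6.1f}"
              f"   backward {np.nanmean(prof.ce_backward_ms[m4]):6.1f}")

    table = ce_table(profiles, window=STAGE4)
    table.to_csv(OUT / "ce_table.tsv", sep="\t", index=False)
    print("\nper-replicate stage-4 CE (ms), ANOVA input:")
    print(table.groupby(["visibility", "direction"], observed=True)["ce_ms"].mean().round(1))

    # a replicate whose diagonal sits at chance through a whole timeframe has
    # undefined CE there; such replicates are dropped (no imputation), as
    # incomplete subjects would be
    bad = table.loc[table["ce_ms"].isna(), "replicate"].unique()
    if len(bad):
        print(f"\ndropping replicate(s) {sorted(bad)} with undefined CE cells")
        table = table[~table["replicate"].isin(bad)]
    if table["replicate"].nunique() >= 2:
        res = ce_anova(table)
        res["anova"].to_csv(OUT / "ce_anova.tsv", sep="\t")
        res["contrasts"].to_csv(OUT / "ce_contrasts.tsv", sep="\t", index=False)
        print("\nANOVA (Visibility x Direction x Timeframe):")
        print(res["anova"].round(4))
        print("\nplanned contrasts (seen vs unseen):")
        print(res["contrasts"].round(4).to_string(index=False))
        print("\nnote: per-replicate CE is noisy at desk scale; a handful of "
              "replicates rarely reaches significance even when the averaged-matrix "
              "signature above is clear")
    else:
        print("fewer than 2 complete replicates; ANOVA skipped")


if __name__ == "__main__":
    main()
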