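"""Temporal generalization, cross-condition transfer, and endurance.

Training a decoder at time t and testing it at every other time t'
diagnoses the temporal structure of the underlying code: a sustained,
static code yields a square block of above-chance generalization, while
a chain of transient codes confines performance to a band around the
diagonal.  Classification Endurance (CE) summarises this as a decoder
half-life: the number of contiguous samples forward/backward from the
training time over which off-diagonal performance stays above 50% of
the diagonal's *above-chance excess*.

CE is measured on the above-chance excess rather than the raw
probability: 50% of a raw 8-class probability (e.g. 0.5 x 0.157 =
0.078) is below the 0.125 chance level, which would make a raw-level
half-life infinite, so the excess-based definition is the only
self-consistent one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .decoding import (
    FoldAssignment,
    _check_folds_cover_classes,
    assign_folds,
    fit_seed,
    make_classifier,
    CLASSIFIER_SPEC,
)
from .epochs import EpochSet

__all__ = [
    "GeneralizationMatrix",
    "EnduranceProfile",
    "CrossConditionCurves",
    "cross_condition_curves",
    "temporal_generalization_matrix",
    "recenter_by_lag",
    "classification_endurance",
    "ce_table",
    "ce_anova",
]


@dataclass
class GeneralizationMatrix:
    """Train-time x test-time mean correct-class probability."""

    values: np.ndarray
    times: np.ndarray
    train_cond: str = ""
    test_cond: str = ""
    trial_cc: np.ndarray | None = None  # trials x train x test correct-class probs

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("generalization matrix must be square in time")


@dataclass
class CrossConditionCurves:
    """Within-condition decoding plus transfer to a disjoint condition."""

    times: np.ndarray
    within_cc: np.ndarray  # per held-out trial of the training condition
    transfer_cc: np.ndarray  # per test-condition trial, fold-averaged
    folds: FoldAssignment

    @property
    def within_curve(self) -> np.ndarray:
        return self.within_cc.mean(axis=0)

    @property
    def transfer_curve(self) -> np.ndarray:
        return self.transfer_cc.mean(axis=0)


def cross_condition_curves(
    epochs: EpochSet,
    labels,
    mask_train,
    mask_test,
    k: int = 15,
    seed: int = 0,
    tol: float = CLASSIFIER_SPEC["tol"],
) -> CrossConditionCurves:
    """Train on one condition's folds; test held-out folds and the other condition.

    Per time sample, the model fit on k-1 folds of the training
    condition is evaluated (a) on the held-out fold and (b) on all
    test-condition trials; the transfer estimate for each test trial is
    the average over the k fold models.  If the two masks are identical
    this is self-transfer: the transfer curve equals the within curve by
    construction.  Partially overlapping conditions are an error.
    """
    mask_train = np.asarray(mask_train, dtype=bool)
    mask_test = np.asarray(mask_test, dtype=bool)
    self_transfer = np.array_equal(mask_train, mask_test)
    if not self_transfer and (mask_train & mask_test).any():
        raise ValueError("training and test conditions overlap")

    labels = np.asarray(labels)
    tr_idx = np.flatnonzero(mask_train)
    te_idx = np.flatnonzero(mask_test)
    if tr_idx.size == 0 or te_idx.size == 0:
        raise ValueError("empty condition")
    folds = assign_folds(tr_idx.size, k, seed)
    y = labels[tr_idx]
    classes = np.unique(y)
    _check_folds_cover_classes(y, folds, classes)
    lut = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([lut[l] for l in y])
    yte_idx = np.array([lut[l] for l in labels[te_idx]])

    X_train_all = epochs.data[tr_idx]
    X_test_all = epochs.data[te_idx]
    n_t = epochs.n_times
    within = np.empty((tr_idx.size, n_t))
    transfer_sum = np.zeros((te_idx.size, n_t))
    for f in range(folds.k):
        tr = folds.train_mask(f)
        te = folds.test_mask(f)
        for t in range(n_t):
            clf = make_classifier(fit_seed(folds.seed, f, t), tol=tol)
            clf.fit(np.ascontiguousarray(X_train_all[tr, :, t]), y[tr])
            p_held = clf.predict_proba(np.ascontiguousarray(X_train_all[te, :, t]))
            within[te, t] = p_held[np.arange(te.sum()), y_idx[te]]
            if self_transfer:
                continue
            p_xfer = clf.predict_proba(np.ascontiguousarray(X_test_all[:, :, t]))
            transfer_sum[:, t] += p_xfer[np.arange(te_idx.size), yte_idx]
    transfer = within.copy() if self_transfer else transfer_sum / folds.k
    return CrossConditionCurves(epochs.times.copy(), within, transfer, folds)


def temporal_generalization_matrix(
    epochs: EpochSet,
    labels,
    folds: FoldAssignment,
    tol: float = CLASSIFIER_SPEC["tol"],
    train_cond: str = "",
    test_cond: str = "",
    keep_trials: bool = True,
) -> GeneralizationMatrix:
    """Train at every t on k-1 folds, test at every t' on the held-out fold.

    Shares the fold assignment and per-(fold, t) seeds with
    :func:`~meegdecode.decoding.decode_timecourse`, so the diagonal of
    the returned matrix reproduces the standard decoding curve exactly.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    _check_folds_cover_classes(labels, folds, classes)
    lut = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([lut[l] for l in labels])

    n, _, n_t = epochs.data.shape
    cc = np.empty((n, n_t, n_t))
    for f in range(folds.k):
        tr = folds.train_mask(f)
        te = folds.test_mask(f)
        te_rows = np.flatnonzero(te)
        y_te = y_idx[te]
        for t in range(n_t):
            clf = make_classifier(fit_seed(folds.seed, f, t), tol=tol)
            clf.fit(np.ascontiguousarray(epochs.data[tr, :, t]), labels[tr])
            for t2 in range(n_t):
                proba = clf.predict_proba(np.ascontiguousarray(epochs.data[te, :, t2]))
                cc[te_rows, t, t2] = proba[np.arange(te_rows.size), y_te]
    values = cc.mean(axis=0)
    return GeneralizationMatrix(values, epochs.times.copy(), train_cond, test_cond,
                                cc if keep_trials else None)


def recenter_by_lag(matrix: GeneralizationMatrix):
    """Re-index values[t, t'] to (t, lag = t' - t); out-of-range lags are NaN.

    Returns (lags_in_samples, surface) with surface shape (n_times, 2*n_times - 1).
    """
    v = matrix.values
    n = v.shape[0]
    lags = np.arange(-(n - 1), n)
    surface = np.full((n, 2 * n - 1), np.nan)
    rows, cols = np.indices((n, n))
    surface[rows, cols - rows + (n - 1)] = v
    return lags, surface


@dataclass
class EnduranceProfile:
    """Forward/backward decoder half-life per training time.

    Values are NaN where the diagonal is at or below chance (CE is
    undefined there, not zero).
    """

    times: np.ndarray
    ce_forward: np.ndarray  # samples
    ce_backward: np.ndarray
    chance: float

    @property
    def dt_ms(self) -> float:
        return float(np.diff(self.times).mean()) if len(self.times) > 1 else np.nan

    @property
    def ce_forward_ms(self) -> np.ndarray:
        return self.ce_forward * self.dt_ms

    @property
    def ce_backward_ms(self) -> np.ndarray:
        return self.ce_backward * self.dt_ms


def classification_endurance(matrix: GeneralizationMatrix, chance: float) -> EnduranceProfile:
    """Count contiguous samples with off-diagonal excess >= 50% of the diagonal excess.

    For a training time t with diagonal excess e(t) = values[t, t] -
    chance > 0, the forward CE is the largest n such that
    values[t, t+i] - chance >= 0.5 e(t) for *all* 1 <= i <= n; an
    isolated sub-threshold dip terminates the run.  Backward is the
    mirror image.
    """
    v = matrix.values
    n = v.shape[0]
    fwd = np.full(n, np.nan)
    bwd = np.full(n, np.nan)
    for t in range(n):
        e = v[t, t] - chance
        if e <= 0:
            continue
        thr = 0.5 * e
        c = 0
        for i in range(1, n - t):
            if v[t, t + i] - chance >= thr:
                c += 1
            else:
                break
        fwd[t] = c
        c = 0
        for i in range(1, t + 1):
            if v[t, t - i] - chance >= thr:
                c += 1
            else:
                break
        bwd[t] = c
    return EnduranceProfile(matrix.times.copy(), fwd, bwd, chance)


def ce_table(
    profiles: dict,
    window: tuple[float, float] = (272.0, 800.0),
    n_frames: int = 5,
) -> pd.DataFrame:
    """Build the replicate x visibility x direction x timeframe CE table.

    ``profiles`` maps (replicate, visibility) -> EnduranceProfile.  CE
    (in ms) is averaged over training times within each of ``n_frames``
    equal half-open subdivisions of ``window``; NaN (undefined) training
    times are excluded from the average.
    """
    edges = np.linspace(window[0], window[1], n_frames + 1)
    rows = []
    for (rep, vis), prof in profiles.items():
        for d, ce_ms in (("forward", prof.ce_forward_ms), ("backward", prof.ce_backward_ms)):
            for frame in range(n_frames):
                m = (prof.times >= edges[frame]) & (prof.times < edges[frame + 1])
                vals = ce_ms[m]
                vals = vals[~np.isnan(vals)]
                rows.append(
                    {"replicate": rep, "visibility": vis, "direction": d,
                     "timeframe": frame + 1, "ce_ms": vals.mean() if vals.size else np.nan}
                )
    return pd.DataFrame(rows)


def ce_anova(table: pd.DataFrame) -> dict:
    """Repeated-measures Visibility x Direction x Timeframe ANOVA on CE.

    Requires a balanced full-factorial table (no imputation).  Returns
    the ANOVA table plus the two planned contrasts (forward and backward
    seen-vs-unseen paired t across replicates).
    """
    required = {"replicate", "visibility", "direction", "timeframe", "ce_ms"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table["ce_ms"].isna().any():
        raise ValueError("CE table contains missing cells; no imputation is performed")
    counts = table.groupby(["visibility", "direction", "timeframe"], observed=True).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced factorial table")
    n_rep = table["replicate"].nunique()
    if n_rep < 2:
        raise ValueError("need >= 2 replicates")

    if np.allclose(table["ce_ms"].std(), 0):
        effects = ["visibility", "direction", "timeframe",
                   "visibility:direction", "visibility:timeframe", "direction:timeframe",
                   "visibility:direction:timeframe"]
        anova = pd.DataFrame({"F Value": 0.0, "Pr > F": 1.0, "Num DF": np.nan, "Den DF": np.nan},
                             index=effects)
        anova.index.name = "Effect"
    else:
        fit = AnovaRM(table, depvar="ce_ms", subject="replicate",
                      within=["visibility", "direction", "timeframe"]).fit()
        anova = fit.anova_table

    contrasts = []
    for d in ("forward", "backward"):
        sub = table[table["direction"] == d]
        piv = sub.pivot_table(index="replicate", columns="visibility", values="ce_ms",
                              observed=True)
        a, b = piv["seen"], piv["unseen"]
        if np.allclose((a - b).std(), 0):
            t, p = (0.0, 1.0) if np.allclose(a, b) else (np.inf * np.sign((a - b).mean()), 0.0)
        else:
            res = stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
        contrasts.append({"direction": d, "mean_seen": a.mean(), "mean_unseen": b.mean(),
                          "t": t, "p": p, "df": len(a) - 1})
    return {"anova": anova, "contrasts": pd.DataFrame(contrasts)}
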