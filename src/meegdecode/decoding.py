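"""Per-timepoint multivariate decoding with calibrated probabilities.

A linear max-margin classifier (SVM, C = 1) is trained separately at
every time sample on the z-scored channel vector, under k-fold
cross-validation (default k = 15), and emits a calibrated posterior
probability for each class.  The per-class probabilities — not hard
labels — are the analysis currency throughout: decoding curves are the
mean posterior assigned to the *true* class.

Probability calibration uses sigmoid (Platt-style) calibration fitted on
internal cross-validated decision values (`CalibratedClassifierCV`,
``ensemble=False``), the scikit-learn successor of libsvm's built-in
probability machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .epochs import EpochSet

__all__ = [
    "FoldAssignment",
    "DecodingResult",
    "WindowStats",
    "assign_folds",
    "decode_timecourse",
    "correct_probabilities",
    "correct_class_series",
    "distance_profile",
    "chance_corrected_mean",
    "window_stats",
    "predicted_class",
]

#: default SVM / calibration settings (cost fixed at 1, no tuning)
CLASSIFIER_SPEC = {
    "model": "linear SVM",
    "C": 1.0,
    "calibration": "sigmoid",
    "calibration_cv": 3,
    "tol": 1e-2,
}


@dataclass
class FoldAssignment:
    """Balanced random partition of trials into k non-overlapping folds."""

    fold_of_trial: np.ndarray
    k: int
    seed: int

    def train_mask(self, fold: int) -> np.ndarray:
        return self.fold_of_trial != fold

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_of_trial == fold


def assign_folds(n_trials: int, k: int = 15, seed: int = 0) -> FoldAssignment:
    """Randomly partition ``n_trials`` into k folds whose sizes differ by <= 1."""
    if n_trials < k:
        raise ValueError(f"cannot make {k} folds from {n_trials} trials")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_trials)
    fold_of = np.empty(n_trials, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(order, k)):
        fold_of[chunk] = f
    return FoldAssignment(fold_of, k, seed)


def fit_seed(master_seed: int, fold: int, t: int) -> int:
    """Deterministic per-(fold, time) seed for the calibration split."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(fold, t))
    return int(ss.generate_state(1)[0] % (2**31))


def make_classifier(seed: int, tol: float = 1e-2) -> CalibratedClassifierCV:
    base = SVC(kernel="linear", C=1.0, tol=tol)
    cv = StratifiedKFold(n_splits=CLASSIFIER_SPEC["calibration_cv"], shuffle=True, random_state=seed)
    return CalibratedClassifierCV(base, method="sigmoid", cv=cv, ensemble=False)


@dataclass
class DecodingResult:
    """Cross-validated calibrated posteriors, trials x classes x time."""

    posteriors: np.ndarray
    classes: np.ndarray
    folds: FoldAssignment
    times: np.ndarray
    classifier_spec: dict = field(default_factory=lambda: dict(CLASSIFIER_SPEC))

    @property
    def n_trials(self) -> int:
        return self.posteriors.shape[0]

    def class_index(self, labels) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[l] for l in np.asarray(labels)])


def _check_folds_cover_classes(labels: np.ndarray, folds: FoldAssignment, classes: np.ndarray) -> None:
    min_needed = CLASSIFIER_SPEC["calibration_cv"]
    for f in range(folds.k):
        train = labels[folds.train_mask(f)]
        missing = set(classes) - set(train)
        if missing:
            raise ValueError(
                f"class(es) {sorted(missing, key=str)} absent from the training set of fold {f}; "
                "rebalance trials across folds"
            )
        counts = pd.Series(train).value_counts()
        if counts.min() < min_needed:
            raise ValueError(
                f"class '{counts.idxmin()}' has only {counts.min()} trial(s) in the training "
                f"set of fold {f}; probability calibration needs >= {min_needed} per class — "
                "add trials or reduce k"
            )


def decode_timecourse(
    epochs: EpochSet,
    labels,
    folds: FoldAssignment,
    tol: float = CLASSIFIER_SPEC["tol"],
) -> DecodingResult:
    """Train/test the per-timepoint classifier under k-fold CV.

    Features at time t are the single-sample vector of all channels'
    values.  Every trial's posterior at every time is produced by a
    model that never saw that trial.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    _check_folds_cover_classes(labels, folds, classes)

    n, _, n_t = epochs.data.shape
    posteriors = np.empty((n, len(classes), n_t))
    for f in range(folds.k):
        tr = folds.train_mask(f)
        te = folds.test_mask(f)
        y_tr = labels[tr]
        for t in range(n_t):
            clf = make_classifier(fit_seed(folds.seed, f, t), tol=tol)
            clf.fit(np.ascontiguousarray(epochs.data[tr, :, t]), y_tr)
            proba = clf.predict_proba(np.ascontiguousarray(epochs.data[te, :, t]))
            # CalibratedClassifierCV orders classes_ like np.unique
            posteriors[te, :, t] = proba
    return DecodingResult(posteriors, classes, folds, epochs.times.copy(),
                          dict(CLASSIFIER_SPEC, tol=tol))


def predicted_class(result: DecodingResult) -> np.ndarray:
    """Hard readout per (trial, time); argmax ties break toward the lowest class index."""
    return result.classes[np.argmax(result.posteriors, axis=1)]


def correct_probabilities(result: DecodingResult, labels) -> np.ndarray:
    """Posterior assigned to the true class, shape (n_trials, n_times)."""
    idx = result.class_index(labels)
    return result.posteriors[np.arange(result.n_trials), idx, :]


def correct_class_series(result: DecodingResult, labels, condition_masks: dict) -> pd.DataFrame:
    """Mean (± sem) correct-class probability over time, per condition.

    ``condition_masks`` maps condition name -> boolean trial mask.
    Raises on an empty condition.
    """
    cc = correct_probabilities(result, labels)
    rows = []
    for name, mask in condition_masks.items():
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"condition '{name}' selects no trials")
        sub = cc[mask]
        mean = sub.mean(axis=0)
        sem = sub.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(sub.shape[1], np.nan)
        rows.append(pd.DataFrame({"condition": name, "time_ms": result.times,
                                  "mean": mean, "sem": sem, "n": n}))
    return pd.concat(rows, ignore_index=True)


def distance_profile(result: DecodingResult, labels) -> np.ndarray:
    """Posterior mass as a function of circular distance to the true location.

    Classes must be the 8 circular locations (45° steps).  Returns a
    (5, n_times) array for distances 0..4; the middle bins pool the two
    symmetric neighbours, so uniform posteriors give
    (0.125, 0.25, 0.25, 0.25, 0.125).
    """
    if not np.array_equal(np.sort(result.classes), np.arange(1, 9)):
        raise ValueError("distance profile requires the circular 8-location label scheme")
    labels = np.asarray(labels)
    class_vals = result.classes.astype(int)
    out = np.zeros((5, result.posteriors.shape[2]))
    for d in range(5):
        mass = np.zeros((result.n_trials, result.posteriors.shape[2]))
        for j, c in enumerate(class_vals):
            dist = np.minimum(np.abs(c - labels), 8 - np.abs(c - labels))
            sel = dist == d
            if sel.any():
                mass[sel] += result.posteriors[sel, j, :]
        out[d] = mass.mean(axis=0)
    return out


def chance_corrected_mean(
    series_correct: np.ndarray,
    series_incorrect: np.ndarray,
    n_correct: int,
    n_incorrect: int,
    n_classes: int = 8,
) -> np.ndarray:
    """Remove the estimated contribution of lucky guesses from a correct-trial curve.

    Among unseen trials, guesses land on the correct location 1/K of the
    time; those lucky-guess trials are assumed to carry only
    incorrect-trial-level information.  With g = n_incorrect * K/(K-1)
    estimated guess trials, g/K of them contaminate the correct set, and
    the informed-trial mean is recovered as
    ``(n_c * S_c - (g/K) * S_i) / (n_c - g/K)``.
    """
    if n_correct <= 0 or n_incorrect < 0:
        raise ValueError("counts must be positive")
    g_correct = n_incorrect / (n_classes - 1)  # = (n_incorrect * K/(K-1)) / K
    if n_correct <= g_correct:
        raise ValueError(
            "degenerate correction: estimated lucky guesses exceed the correct-trial count"
        )
    s_c = np.asarray(series_correct, dtype=float)
    s_i = np.asarray(series_incorrect, dtype=float)
    return (n_correct * s_c - g_correct * s_i) / (n_correct - g_correct)


@dataclass
class WindowStats:
    """Stage-windowed summary statistics across replicates."""

    per_window: pd.DataFrame
    paired: pd.DataFrame
    windows: dict
    chance: float


def _one_sample(values: np.ndarray, popmean: float, alternative: str):
    sd = values.std(ddof=1)
    if sd == 0:
        diff = values.mean() - popmean
        if diff == 0:
            return 0.0, 1.0
        warnings.warn("zero variance across replicates; reporting p -> 0", RuntimeWarning)
        return np.inf * np.sign(diff), 0.0
    res = stats.ttest_1samp(values, popmean, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def window_stats(
    series: dict,
    times: np.ndarray,
    windows: dict,
    chance: float,
    pairs: list | None = None,
    one_tailed: bool = False,
) -> WindowStats:
    """Per-window means, one-sample t vs chance, and paired condition contrasts.

    ``series`` maps condition -> (n_replicates, n_times) array; all
    conditions must share the replicate axis for paired tests.
    ``one_tailed`` applies to the paired contrasts (alternative:
    first > second) and is flagged in the output.
    """
    times = np.asarray(times)
    rows, paired_rows = [], []
    win_masks = {}
    for wname, (a, b) in windows.items():
        mask = (times >= a) & (times < b)
        if not mask.any():
            raise ValueError(f"window '{wname}' [{a}, {b}) contains no samples")
        win_masks[wname] = mask

    for wname, mask in win_masks.items():
        for cond, arr in series.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if arr.shape[0] < 2:
                raise ValueError("window_stats needs >= 2 replicates")
            vals = arr[:, mask].mean(axis=1)
            t, p = _one_sample(vals, chance, "two-sided")
            rows.append(
                {"window": wname, "condition": cond, "mean": vals.mean(),
                 "sem": vals.std(ddof=1) / np.sqrt(len(vals)), "t": t, "p": p,
                 "df": len(vals) - 1}
            )
        for ca, cb in pairs or []:
            va = np.atleast_2d(series[ca])[:, mask].mean(axis=1)
            vb = np.atleast_2d(series[cb])[:, mask].mean(axis=1)
            t, p = _one_sample(va - vb, 0.0, "greater" if one_tailed else "two-sided")
            paired_rows.append(
                {"window": wname, "cond_a": ca, "cond_b": cb, "mean_diff": (va - vb).mean(),
                 "t": t, "p": p, "df": len(va) - 1, "one_tailed": one_tailed}
            )
    return WindowStats(pd.DataFrame(rows), pd.DataFrame(paired_rows), dict(windows), chance)
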