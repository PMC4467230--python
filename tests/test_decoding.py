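"""Fold assignment, cross-validated decoding, curves, and window statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from meegdecode import (
    DecodingResult,
    assign_folds,
    chance_corrected_mean,
    correct_class_series,
    correct_probabilities,
    decode_timecourse,
    distance_profile,
    window_stats,
)
from meegdecode.decoding import FoldAssignment, fit_seed, make_classifier

from .conftest import STAGES, toy_epochs


class TestFoldAssignment:
    def test_thirty_trials_fifteen_folds(self):
        fa = assign_folds(30, 15, seed=0)
        sizes = np.bincount(fa.fold_of_trial, minlength=15)
        assert (sizes == 2).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(15, 120), k=st.integers(2, 15), seed=st.integers(0, 1000))
    def test_partition_properties(self, n, k, seed):
        """Folds are exhaustive, disjoint, and balanced to within one trial."""
        fa = assign_folds(n, k, seed)
        assert len(fa.fold_of_trial) == n
        sizes = np.bincount(fa.fold_of_trial, minlength=k)
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1

    def test_deterministic(self):
        assert np.array_equal(assign_folds(40, 5, 9).fold_of_trial,
                              assign_folds(40, 5, 9).fold_of_trial)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            assign_folds(10, 15, 0)


class TestDecodeTimecourse:
    def _separable_epochs(self, n_per=12, n_ch=8, n_t=4, seed=0):
        rng = np.random.default_rng(seed)
        locs = np.repeat([1, 5], n_per)
        pats = rng.standard_normal((2, n_ch))
        data = 0.3 * rng.standard_normal((2 * n_per, n_ch, n_t))
        data += 2.0 * pats[(locs == 5).astype(int)][:, :, None]
        return toy_epochs(data, locations=locs), locs

    def test_matches_brute_force_retrain_oracle(self):
        """Each trial's posterior equals an independent per-fold refit."""
        ep, locs = self._separable_epochs()
        folds = assign_folds(ep.n_trials, 4, seed=1)
        res = decode_timecourse(ep, locs, folds)
        for f in range(4):
            tr, te = folds.train_mask(f), folds.test_mask(f)
            for t in range(ep.n_times):
                clf = make_classifier(fit_seed(folds.seed, f, t))
                clf.fit(np.ascontiguousarray(ep.data[tr, :, t]), locs[tr])
                proba = clf.predict_proba(np.ascontiguousarray(ep.data[te, :, t]))
                assert np.array_equal(res.posteriors[te, :, t], proba)

    def test_posteriors_normalized_and_out_of_fold(self):
        ep, locs = self._separable_epochs()
        folds = assign_folds(ep.n_trials, 4, seed=2)
        res = decode_timecourse(ep, locs, folds)
        sums = res.posteriors.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_separable_data_decoded_confidently(self):
        ep, locs = self._separable_epochs()
        folds = assign_folds(ep.n_trials, 4, seed=3)
        cc = correct_probabilities(decode_timecourse(ep, locs, folds), locs)
        assert (cc > 0.5).all()

    def test_missing_class_in_training_fold_advises_rebalancing(self):
        ep, locs = self._separable_epochs(n_per=3)
        fold_of = np.array([0, 0, 0, 1, 1, 1])  # fold 1's complement lacks class 5
        folds = FoldAssignment(fold_of, 2, seed=0)
        with pytest.raises(ValueError, match="rebalance"):
            decode_timecourse(ep, locs, folds)

    def test_duplicated_trials_in_mirror_folds_score_symmetrically(self):
        """Two copies of each trial in complementary folds get near-identical posteriors."""
        ep, locs = self._separable_epochs(n_per=6, n_t=2)
        # duplicate: trials 0..11 and 12..23 are identical sets
        data = np.concatenate([ep.data, ep.data])
        locs2 = np.concatenate([locs, locs])
        ep2 = toy_epochs(data, locations=locs2)
        fold_of = np.array([0] * 12 + [1] * 12)
        res = decode_timecourse(ep2, locs2, FoldAssignment(fold_of, 2, seed=4))
        diff = np.abs(res.posteriors[:12] - res.posteriors[12:])
        assert diff.max() < 0.1  # calibration splits differ across folds


class TestCurvesAndProfiles:
    def _uniform_result(self, n=10, n_t=6):
        post = np.full((n, 8, n_t), 0.125)
        folds = assign_folds(n, 2, 0)
        return DecodingResult(post, np.arange(1, 9), folds, np.arange(n_t) * 15.625)

    def test_uniform_posteriors_flat_chance_series(self):
        res = self._uniform_result()
        labels = (np.arange(10) % 8) + 1
        df = correct_class_series(res, labels, {"all": np.ones(10, bool)})
        assert np.allclose(df["mean"], 0.125)

    def test_single_trial_condition_returns_own_trace(self):
        res = self._uniform_result()
        res.posteriors[3, :, :] = 0
        res.posteriors[3, 2, :] = 1.0  # trial 3 certain of class 3
        labels = np.full(10, 3)
        mask = np.zeros(10, bool)
        mask[3] = True
        df = correct_class_series(res, labels, {"one": mask})
        assert np.allclose(df["mean"], 1.0)

    def test_empty_condition_errors(self):
        res = self._uniform_result()
        with pytest.raises(ValueError):
            correct_class_series(res, np.ones(10, int), {"none": np.zeros(10, bool)})

    def test_distance_profile_uniform(self):
        """Uniform posteriors give (0.125, 0.25, 0.25, 0.25, 0.125) after pooling."""
        res = self._uniform_result()
        labels = (np.arange(10) % 8) + 1
        prof = distance_profile(res, labels)
        assert np.allclose(prof.mean(axis=1), [0.125, 0.25, 0.25, 0.25, 0.125])

    def test_distance_profile_perfect_decoder(self):
        res = self._uniform_result()
        labels = (np.arange(10) % 8) + 1
        res.posteriors[:] = 0
        for i, l in enumerate(labels):
            res.posteriors[i, l - 1, :] = 1.0
        prof = distance_profile(res, labels)
        assert np.allclose(prof[0], 1.0) and np.allclose(prof[1:], 0.0)

    def test_distance_profile_matches_brute_force_grouping(self):
        """Analytic distance-tuned posteriors: strictly decreasing, oracle-equal."""
        rng = np.random.default_rng(5)
        n, n_t = 16, 3
        labels = (np.arange(n) % 8) + 1
        post = np.empty((n, 8, n_t))
        for i, l in enumerate(labels):
            d = np.minimum(np.abs(np.arange(1, 9) - l), 8 - np.abs(np.arange(1, 9) - l))
            w = np.exp(-0.8 * d)
            post[i] = (w / w.sum())[:, None]
        res = DecodingResult(post, np.arange(1, 9), assign_folds(n, 2, 0), np.arange(n_t) * 1.0)
        prof = distance_profile(res, labels)
        # independent loop oracle
        oracle = np.zeros((5, n_t))
        for d in range(5):
            acc = np.zeros((n, n_t))
            for i, l in enumerate(labels):
                for j, c in enumerate(range(1, 9)):
                    dist = min(abs(c - l), 8 - abs(c - l))
                    if dist == d:
                        acc[i] += post[i, j]
            oracle[d] = acc.mean(axis=0)
        assert np.allclose(prof, oracle)
        per_class = prof.mean(axis=1) / np.array([1, 2, 2, 2, 1])
        assert np.all(np.diff(per_class) < 0)


class TestChanceCorrection:
    def test_no_incorrect_trials_is_identity(self):
        s = np.linspace(0.1, 0.2, 5)
        assert np.allclose(chance_corrected_mean(s, s * 0 + 0.1, 40, 0), s)

    def test_equal_series_is_identity(self):
        s = np.linspace(0.1, 0.2, 5)
        assert np.allclose(chance_corrected_mean(s, s, 30, 14), s)

    def test_degenerate_counts_error(self):
        with pytest.raises(ValueError):
            chance_corrected_mean(np.ones(3), np.ones(3), 2, 70)

    def test_mixture_recovery(self):
        """Brute-force mixture: corrected mean recovers the informed level."""
        rng = np.random.default_rng(6)
        a, b = 0.20, 0.14  # informed vs guess decoding level
        n_informed, n_guess = 70_000, 30_000
        informed = rng.normal(a, 0.05, n_informed)
        guess = rng.normal(b, 0.05, n_guess)
        lucky = rng.random(n_guess) < 1 / 8
        correct = np.concatenate([informed, guess[lucky]])
        incorrect = guess[~lucky]
        est = chance_corrected_mean(np.array([correct.mean()]), np.array([incorrect.mean()]),
                                    len(correct), len(incorrect))[0]
        assert abs(est - a) < 0.002  # ~several s.e. of the informed mean


class TestWindowStats:
    def test_all_chance_gives_t0_p1(self):
        series = {"c": np.full((4, 64), 0.125)}
        times = np.arange(64) * 15.625
        ws = window_stats(series, times, STAGES, chance=0.125)
        assert np.allclose(ws.per_window["t"], 0.0)
        assert np.allclose(ws.per_window["p"], 1.0)

    def test_zero_variance_offset_warns(self):
        series = {"c": np.full((4, 64), 0.2)}
        times = np.arange(64) * 15.625
        with pytest.warns(RuntimeWarning):
            ws = window_stats(series, times, STAGES, chance=0.125)
        assert (ws.per_window["p"] == 0).all()

    def test_stage4_gain_detected_with_power(self):
        """Injected late gain: paired t significant in stage 4 in >=90% of runs,
        and false-positive rate in the earlier stages near the nominal 5%."""
        times = np.arange(-13, 51) * 15.625  # -203..781 ms
        hits4, hits_early = 0, 0
        n_runs = 100
        for r in range(n_runs):
            rng = np.random.default_rng(100 + r)
            base = 0.13 + 0.002 * rng.standard_normal((12, len(times)))
            seen = base + 0.004 * rng.standard_normal((12, len(times)))
            seen[:, (times >= 271) & (times < 800)] += 0.01
            unseen = base + 0.004 * rng.standard_normal((12, len(times)))
            ws = window_stats({"seen": seen, "unseen": unseen}, times, STAGES, 0.125,
                              pairs=[("seen", "unseen")])
            p = ws.paired.set_index("window")["p"]
            hits4 += p["stage4"] < 0.05
            hits_early += (p[["stage1", "stage2", "stage3"]] < 0.05).any()
        assert hits4 >= 90
        assert hits_early <= 25


class TestConditionCurvesOnSyntheticWorld:
    def test_seen_unseen_diverge_only_late(self, small_epochs, small_decode):
        """Seen and unseen decoding match in stages 1-3 and split in stage 4."""
        res, labels = small_decode
        cc = correct_probabilities(res, labels)
        seen = small_epochs.trials["seen"].to_numpy(bool)
        corr = small_epochs.trials["correct"].to_numpy(bool)
        times = small_epochs.times
        s = cc[seen & corr]
        u = cc[~seen & corr]
        for st_name in ("stage1", "stage2", "stage3"):
            a, b = STAGES[st_name]
            m = (times >= a) & (times < b)
            assert abs(s[:, m].mean() - u[:, m].mean()) < 0.02, st_name
        m4 = (times >= 271) & (times < 800)
        assert s[:, m4].mean() - u[:, m4].mean() > 0.02

    def test_above_chance_after_early_onset(self, small_epochs, small_decode):
        res, labels = small_decode
        cc = correct_probabilities(res, labels)
        times = small_epochs.times
        assert cc[:, times < 100].mean() == pytest.approx(0.125, abs=0.01)
        assert cc[:, (times >= 130) & (times < 800)].mean() > 0.14
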