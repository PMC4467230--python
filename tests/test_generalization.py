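"""Temporal generalization, lag recentering, endurance, and the CE ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from meegdecode import (
    GeneralizationMatrix,
    assign_folds,
    ce_anova,
    ce_table,
    classification_endurance,
    correct_probabilities,
    cross_condition_curves,
    decode_timecourse,
    recenter_by_lag,
    temporal_generalization_matrix,
)
from meegdecode.generalization import EnduranceProfile

from .conftest import toy_epochs


def _mat(values, dt=15.625, t0=0.0):
    values = np.asarray(values, dtype=float)
    return GeneralizationMatrix(values, t0 + np.arange(len(values)) * dt)


def ce_oracle(values: np.ndarray, chance: float):
    """Exhaustive run-length scan, independent of the implementation."""
    n = len(values)
    fwd = np.full(n, np.nan)
    bwd = np.full(n, np.nan)
    for t in range(n):
        e = values[t, t] - chance
        if e <= 0:
            continue
        thr = 0.5 * e
        run = 0
        for i in range(1, n - t):
            if values[t, t + i] - chance >= thr:
                run = i
            else:
                break
        fwd[t] = run
        run = 0
        for i in range(1, t + 1):
            if values[t, t - i] - chance >= thr:
                run = i
            else:
                break
        bwd[t] = run
    return fwd, bwd


class TestRecenterByLag:
    def test_lag_zero_row_equals_diagonal(self):
        rng = np.random.default_rng(0)
        m = _mat(rng.random((7, 7)))
        lags, surf = recenter_by_lag(m)
        assert np.array_equal(surf[:, lags == 0].ravel(), np.diag(m.values))

    def test_symmetric_matrix_symmetric_surface(self):
        rng = np.random.default_rng(1)
        a = rng.random((6, 6))
        m = _mat((a + a.T) / 2)
        lags, surf = recenter_by_lag(m)
        mean_by_lag = np.nanmean(surf, axis=0)
        assert np.allclose(mean_by_lag, mean_by_lag[::-1], equal_nan=True)

    def test_matches_exhaustive_reindexing(self):
        rng = np.random.default_rng(2)
        m = _mat(rng.random((5, 5)))
        lags, surf = recenter_by_lag(m)
        for t in range(5):
            for t2 in range(5):
                assert surf[t, list(lags).index(t2 - t)] == m.values[t, t2]


class TestClassificationEndurance:
    def test_hand_counted_example(self):
        """Diagonal excess 0.08; forward excesses 0.07, 0.05, 0.03, 0.01 -> CE 2."""
        chance = 0.125
        row = np.array([0.205, 0.195, 0.175, 0.155, 0.135])
        v = np.full((5, 5), chance)
        v[0] = row
        np.fill_diagonal(v, chance + 0.08)
        v[0, 0] = 0.205
        prof = classification_endurance(_mat(v), chance)
        assert prof.ce_forward[0] == 2

    def test_flat_matrix_reaches_epoch_edges(self):
        v = np.full((6, 6), 0.2)
        prof = classification_endurance(_mat(v), 0.125)
        assert np.array_equal(prof.ce_forward, [5, 4, 3, 2, 1, 0])
        assert np.array_equal(prof.ce_backward, [0, 1, 2, 3, 4, 5])

    def test_diagonal_at_chance_is_undefined_not_zero(self):
        v = np.full((4, 4), 0.125)
        prof = classification_endurance(_mat(v), 0.125)
        assert np.isnan(prof.ce_forward).all()

    def test_ms_conversion(self):
        v = np.full((4, 4), 0.5)
        prof = classification_endurance(_mat(v, dt=15.625), 0.4)
        assert prof.ce_forward_ms[0] == pytest.approx(3 * 15.625)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), shift=st.floats(-0.3, 0.3))
    def test_invariant_to_joint_constant_shift(self, seed, shift):
        rng = np.random.default_rng(seed)
        v = rng.random((8, 8)) * 0.3 + 0.1
        a = classification_endurance(_mat(v), 0.125)
        b = classification_endurance(_mat(v + shift), 0.125 + shift)
        assert np.array_equal(a.ce_forward, b.ce_forward, equal_nan=True)
        assert np.array_equal(a.ce_backward, b.ce_backward, equal_nan=True)


class TestCrossCondition:
    def _epochs(self, seed=3):
        rng = np.random.default_rng(seed)
        n, n_ch, n_t = 48, 8, 5
        locs = np.tile([1, 5], n // 2)
        seen = np.arange(n) % 4 < 2
        pats = rng.standard_normal((2, n_ch))
        data = 0.5 * rng.standard_normal((n, n_ch, n_t))
        data += 1.5 * pats[(locs == 5).astype(int)][:, :, None]
        return toy_epochs(data, locations=locs, seen=seen), locs, seen

    def test_self_transfer_equals_within(self):
        ep, locs, seen = self._epochs()
        res = cross_condition_curves(ep, locs, seen, seen, k=4, seed=0)
        assert np.array_equal(res.within_cc, res.transfer_cc)

    def test_partial_overlap_errors(self):
        ep, locs, seen = self._epochs()
        other = seen.copy()
        other[:4] = ~other[:4]
        with pytest.raises(ValueError, match="overlap"):
            cross_condition_curves(ep, locs, seen, other, k=4, seed=0)

    def test_shared_code_transfers_fully(self):
        """When both conditions carry the same patterns, transfer matches within."""
        ep, locs, seen = self._epochs()
        res = cross_condition_curves(ep, locs, seen, ~seen, k=4, seed=0)
        assert abs(res.within_curve.mean() - res.transfer_curve.mean()) < 0.05
        assert res.within_curve.mean() > 0.8


class TestTemporalGeneralization:
    def test_diagonal_equals_decode_curve_bitwise(self):
        rng = np.random.default_rng(4)
        n, n_ch, n_t = 32, 6, 8
        locs = np.tile([1, 5], n // 2)
        pats = rng.standard_normal((2, n_ch))
        data = rng.standard_normal((n, n_ch, n_t)) + pats[(locs == 5).astype(int)][:, :, None]
        ep = toy_epochs(data, locations=locs)
        folds = assign_folds(n, 4, seed=5)
        mat = temporal_generalization_matrix(ep, locs, folds)
        res = decode_timecourse(ep, locs, folds)
        curve = correct_probabilities(res, locs).mean(axis=0)
        assert np.array_equal(np.diag(mat.values), curve)

    def test_static_code_gives_square_block(self):
        """A pattern sustained over [a, b] generalizes across the whole block."""
        rng = np.random.default_rng(6)
        n, n_ch, n_t = 48, 8, 10
        locs = np.tile([1, 5], n // 2)
        pats = rng.standard_normal((2, n_ch))
        data = 0.4 * rng.standard_normal((n, n_ch, n_t))
        active = slice(3, 8)
        data[:, :, active] += 2.0 * pats[(locs == 5).astype(int)][:, :, None]
        ep = toy_epochs(data, locations=locs)
        mat = temporal_generalization_matrix(ep, locs, assign_folds(n, 4, seed=7))
        block = mat.values[active, active]
        outside = mat.values[:3, :3]
        assert block.min() > 0.8
        assert abs(outside.mean() - 0.5) < 0.1

    def test_pure_noise_is_chance_everywhere(self):
        rng = np.random.default_rng(8)
        n = 48
        locs = np.tile([1, 5], n // 2)
        ep = toy_epochs(rng.standard_normal((n, 8, 8)), locations=locs)
        mat = temporal_generalization_matrix(ep, locs, assign_folds(n, 4, seed=9))
        assert abs(mat.values.mean() - 0.5) < 0.03


class TestCeAnova:
    def _table(self, rng, delta_vis=0.0, sigma=10.0, n_rep=8):
        rows = []
        for rep in range(n_rep):
            for vis in ("seen", "unseen"):
                for d in ("forward", "backward"):
                    for tf in range(1, 6):
                        ce = 150 + (delta_vis if vis == "unseen" else 0) + rng.normal(0, sigma)
                        rows.append({"replicate": rep, "visibility": vis, "direction": d,
                                     "timeframe": tf, "ce_ms": ce})
        return pd.DataFrame(rows)

    def test_zero_variance_reports_no_effect(self):
        rows = self._table(np.random.default_rng(0), sigma=0.0)
        res = ce_anova(rows)
        assert (res["anova"]["F Value"] == 0).all()
        assert (res["anova"]["Pr > F"] == 1).all()

    def test_unbalanced_table_errors(self):
        t = self._table(np.random.default_rng(1))
        with pytest.raises(ValueError, match="balanced|unbalanced"):
            ce_anova(t.iloc[:-3])

    def test_injected_visibility_effect_detected(self):
        """delta = 80 ms against sigma = 10 ms: significant at alpha 0.01 in >=95/100 runs."""
        hits = 0
        for r in range(100):
            t = self._table(np.random.default_rng(1000 + r), delta_vis=80.0)
            res = ce_anova(t)
            hits += res["anova"].loc["visibility", "Pr > F"] < 0.01
        assert hits >= 95

    def test_null_pvalues_uniform(self):
        """Permutation-style null: visibility p-values are U(0,1) (KS, alpha 0.01)."""
        ps = []
        for r in range(200):
            t = self._table(np.random.default_rng(5000 + r))
            ps.append(ce_anova(t)["anova"].loc["visibility", "Pr > F"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planned_contrasts_direction(self):
        rng = np.random.default_rng(2)
        t = self._table(rng, delta_vis=80.0, sigma=5.0)
        res = ce_anova(t)
        con = res["contrasts"].set_index("direction")
        assert (con["mean_unseen"] > con["mean_seen"]).all()
        assert (con["p"] < 0.01).all()


def test_ce_table_timeframes():
    times = 272.0 + np.arange(20) * 26.4  # spans 272..800
    prof = EnduranceProfile(times, np.arange(20.0), np.arange(20.0)[::-1], 0.5)
    table = ce_table({(0, "seen"): prof}, window=(272.0, 800.0), n_frames=5)
    assert len(table) == 10  # 2 directions x 5 frames
    fwd = table[table["direction"] == "forward"].sort_values("timeframe")["ce_ms"]
    assert fwd.is_monotonic_increasing
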