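"""Cross-recurrence core: embedding, line metrics, parameter selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dyadsync.crqa import (CRQAConfig, RadiusCalibrationError,
                           RecurrenceMatrix, calibrate_radius,
                           compute_metrics, cross_recurrence, diagonal_lines,
                           embed, run_crqa, select_delay, select_dim,
                           vertical_lines)
from dyadsync.pipeline import crqa_table, prepare_inputs
from dyadsync.synthetic import DesignConfig, generate_dataset
from dyadsync.traces import DegenerateSignalError

from oracle import brute_metrics

# The worked 5x5 matrix: ones at (1,1),(2,2),(3,3),(1,4),(4,1) (1-based) —
# one main-diagonal run of length 3 plus two isolated points.
FIVE = np.zeros((5, 5), dtype=bool)
for i, j in [(0, 0), (1, 1), (2, 2), (0, 3), (3, 0)]:
    FIVE[i, j] = True


class TestEmbed:
    def test_delay1_dim2(self):
        out = embed([1, 2, 3, 4, 5], 1, 2)
        assert out.tolist() == [[1, 2], [2, 3], [3, 4], [4, 5]]

    def test_dim1_is_identity(self, rng):
        x = rng.normal(size=20)
        assert np.array_equal(embed(x, 3, 1).ravel(), x)

    def test_delay2_dim3(self):
        out = embed(np.arange(1, 8), 2, 3)
        assert out.tolist() == [[1, 3, 5], [2, 4, 6], [3, 5, 7]]

    def test_too_short_reports_minimum(self):
        with pytest.raises(ValueError, match="at least 21"):
            embed(np.arange(10), 10, 3)


class TestCrossRecurrence:
    def test_infinite_radius_all_ones(self, rng):
        X = embed(rng.normal(size=30), 1, 2)
        R = cross_recurrence(X, X, radius=1e9)
        assert R.R.all() and compute_metrics(R).rr == 1.0

    def test_tiny_radius_all_zeros(self, rng):
        X = embed(rng.normal(size=30), 1, 2)
        Y = embed(rng.normal(size=30), 1, 2)
        assert not cross_recurrence(X, Y, radius=1e-12).R.any()

    def test_self_comparison_has_unit_diagonal(self, rng):
        X = embed(rng.normal(size=30), 1, 2)
        R = cross_recurrence(X, X, radius=1e-9)
        assert np.all(np.diag(R.R))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            cross_recurrence(rng.normal(size=(5, 2)),
                             rng.normal(size=(5, 3)), 1.0)


class TestLineHistograms:
    def test_worked_example_diagonals(self):
        hist = diagonal_lines(FIVE, lmin=1)
        assert hist == {3: 1, 1: 2}

    def test_identity_matrix_single_run(self):
        hist = diagonal_lines(np.eye(6, dtype=bool), lmin=1)
        assert hist == {6: 1}

    def test_empty_matrix_empty_histogram(self):
        assert diagonal_lines(np.zeros((4, 4), bool)) == {}

    def test_worked_example_no_vertical_runs(self):
        hist = vertical_lines(FIVE, vmin=2)
        assert hist == {}

    def test_full_column(self):
        M = np.zeros((5, 3), bool)
        M[:, 1] = True
        assert vertical_lines(M, vmin=1) == {5: 1}

    def test_all_ones_3x3_vertical(self):
        assert vertical_lines(np.ones((3, 3), bool), vmin=1) == {3: 3}


class TestComputeMetrics:
    def test_worked_example_metrics(self):
        m = compute_metrics(FIVE)
        assert m.rr == pytest.approx(5 / 25)
        assert m.det == pytest.approx(3 / 5)
        assert m.lam == 0.0
        assert m.maxl == 3
        assert m.rentr == 0.0

    def test_all_ones(self):
        # the two corner diagonals have length 1 < lmin, so DET is 47/49,
        # not 1: the numerator drops them, the denominator keeps them
        m = compute_metrics(np.ones((7, 7), bool))
        assert (m.rr, m.lam, m.maxl) == (1.0, 1.0, 7)
        assert m.det == pytest.approx(47 / 49)

    def test_all_zeros_flagged_degenerate(self):
        m = compute_metrics(np.zeros((7, 7), bool))
        assert m.degenerate
        assert (m.rr, m.det, m.lam, m.maxl, m.rentr) == (0, 0, 0, 0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(arrays(bool, st.tuples(st.integers(1, 12), st.integers(1, 12))))
    def test_matches_brute_force_enumeration(self, M):
        """DET/LAM/maxL/rENTR agree exactly with cell-by-cell enumeration."""
        got = compute_metrics(M)
        want = brute_metrics(M.tolist())
        assert got.rr == pytest.approx(want["rr"])
        assert got.det == pytest.approx(want["det"])
        assert got.lam == pytest.approx(want["lam"])
        assert got.maxl == want["maxl"]
        assert got.rentr == pytest.approx(want["rentr"])

    def test_transpose_symmetry(self, rng):
        """Swapping the two signals transposes the matrix: RR, DET and maxL
        are invariant; LAM of the transpose equals the horizontal-line LAM
        of the original."""
        M = rng.random((40, 40)) < 0.1
        a, b = compute_metrics(M), compute_metrics(M.T)
        assert a.rr == b.rr and a.det == pytest.approx(b.det)
        assert a.maxl == b.maxl
        horiz = vertical_lines(M.T, vmin=1)   # horizontal runs of M
        lam_h = sum(v * c for v, c in horiz.items() if v >= 2) / M.sum()
        assert b.lam == pytest.approx(lam_h)


class TestDelaySelection:
    def test_sinusoid_first_minimum_near_quarter_period(self):
        # lightly dithered: an exactly periodic sine has only 32 distinct
        # values, which degenerates the equiprobable binning
        t = np.arange(2048)
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * t / 32) + 0.1 * rng.normal(size=t.size)
        assert abs(select_delay(x, max_lag=30) - 8) <= 2

    def test_iid_noise_returns_lag_in_range(self, rng):
        d = select_delay(rng.normal(size=1024), max_lag=20)
        assert 1 <= d <= 20

    def test_pair_rule_takes_maximum(self, rng):
        from dyadsync.crqa import pair_delay

        t = np.arange(2048)
        slow = np.sin(2 * np.pi * t / 64)
        fast = np.sin(2 * np.pi * t / 16)
        d_pair = pair_delay(fast, slow, max_lag=40)
        assert d_pair == max(select_delay(fast, 40), select_delay(slow, 40))
        assert d_pair == select_delay(slow, 40)

    def test_max_lag_too_small_rejected(self, rng):
        with pytest.raises(ValueError, match="max_lag"):
            select_delay(rng.normal(size=100), max_lag=1)


class TestDimSelection:
    def test_white_noise_needs_high_dimension(self, rng):
        x = rng.normal(size=1500)
        assert select_dim(x, delay=1) >= 3

    def test_noiseless_sinusoid_low_dimension(self):
        t = np.arange(2048)
        x = np.sin(2 * np.pi * t / 32)
        assert select_dim(x, delay=8) <= 3

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateSignalError):
            select_dim(np.ones(500), delay=2)


class TestRadiusCalibration:
    def test_band_achieved_on_synthetic_dyad(self, small_dataset):
        rec = small_dataset.dyads[0].blocks[0]
        prep = prepare_inputs(small_dataset, compute_alt=False)
        _, _, x, y = prep.pairs[0]
        X, Y = embed(x, 4, 3), embed(y, 4, 3)
        radius, rr = calibrate_radius(X, Y)
        assert 0.02 <= rr <= 0.04
        assert radius > 0

    def test_constant_series_band_unattainable(self):
        X = np.zeros((50, 2))
        with pytest.raises(RadiusCalibrationError) as err:
            calibrate_radius(X, X)
        assert err.value.achieved_rr in (0.0, 1.0)

    def test_rr_monotone_in_radius(self, rng):
        X = embed(rng.normal(size=200), 2, 3)
        Y = embed(rng.normal(size=200), 2, 3)
        radii = np.sort(rng.uniform(0, 4, size=20))
        rrs = [compute_metrics(cross_recurrence(X, Y, r)).rr for r in radii]
        assert all(a <= b for a, b in zip(rrs, rrs[1:]))


class TestRunCRQA:
    def test_identical_signals_full_diagonal(self, rng):
        x = rng.normal(size=400).cumsum()  # smooth-ish, non-constant
        x = (x - x.mean()) / x.std(ddof=1)
        m = run_crqa(x, x.copy())
        n_emb = len(x) - (m.params.dim - 1) * m.params.delay
        assert m.maxl == n_emb

    def test_coupled_dyads_have_higher_determinism(self):
        """Fully coupled pairs show more diagonal structure than uncoupled."""
        dets = {}
        for kappa, seed in ((0.0, 50), (1.0, 51)):
            ds = generate_dataset(
                DesignConfig(n_dyads=20, n_blocks=1, sample_rate=8, seed=seed),
                coupling_sampler=lambda rng: kappa, seed=seed)
            prep = prepare_inputs(ds, crqa_crop_s=144.0, compute_alt=False)
            met, _ = crqa_table(prep)
            dets[kappa] = met["det"].mean()
        assert dets[1.0] > dets[0.0]

    def test_pipeline_deterministic(self, small_dataset):
        prep = prepare_inputs(small_dataset, compute_alt=False)
        _, _, x, y = prep.pairs[0]
        a, b = run_crqa(x, y), run_crqa(x, y)
        assert a.as_dict() == b.as_dict()

    def test_every_metric_tracks_coupling(self):
        """Pooled over uniformly drawn kappa, each of the four metrics rises
        with the true coupling (Spearman, p < 0.01)."""
        import pandas as pd
        from scipy import stats

        pooled = []
        for seed in (520, 521):
            ds = generate_dataset(DesignConfig(n_dyads=69, n_blocks=1,
                                               sample_rate=8, seed=seed),
                                  seed=seed)
            prep = prepare_inputs(ds, crqa_crop_s=144.0, compute_alt=False)
            met, _ = crqa_table(prep)
            pooled.append(met.merge(ds.ground_truth(), on="dyad_id"))
        allm = pd.concat(pooled)
        for col in ("det", "lam", "maxl", "rentr"):
            rho, p = stats.spearmanr(allm["kappa"], allm[col])
            assert rho > 0 and p < 0.01, (col, rho, p)
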