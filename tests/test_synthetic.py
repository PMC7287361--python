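"""Generator tests: schedules, SCR kernels, coupling, whole datasets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadsync.preprocess import downsample, score_phase, zscore
from dyadsync.synthetic import (CouplingConfig, DesignConfig, EventResponse,
                                SCRKernel, default_kernels, generate_dataset,
                                make_schedule, scr_kernel_eval,
                                synth_demonstrator_trace,
                                synth_observer_trace)

from conftest import quiet_coupling


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

class TestSchedule:
    def test_learning_phase_counts(self, rng):
        sched = make_schedule(DesignConfig(), 1, rng)
        learn = sched.learning_trials
        assert sum(t.cs == "plus" for t in learn) == 6
        assert sum(t.cs == "minus" for t in learn) == 6

    def test_four_shocked_csplus(self, rng):
        sched = make_schedule(DesignConfig(), 1, rng)
        shocked = [t for t in sched.learning_trials if t.shock]
        assert len(shocked) == 4
        assert all(t.cs == "plus" for t in shocked)

    def test_degenerate_iti_gives_fixed_spacing(self, rng):
        design = DesignConfig(iti_range=(10.0, 10.0))
        sched = make_schedule(design, 1, rng)
        onsets = [t.onset for t in sched.learning_trials]
        gaps = np.diff(onsets)
        assert np.allclose(gaps, 10.0 + design.cs_duration)

    def test_testing_phase_structure(self, rng):
        sched = make_schedule(DesignConfig(), 1, rng)
        test = sched.testing_trials
        assert sum(t.cs == "plus" for t in test) == 7
        assert sum(t.cs == "minus" for t in test) == 7
        shocked = [t for t in test if t.shock]
        assert shocked == [[t for t in test if t.cs == "plus"][-1]]

    def test_too_many_shocks_rejected(self):
        with pytest.raises(ValueError, match="n_shocked_csplus"):
            DesignConfig(n_shocked_csplus=7)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_schedule_invariants_hold_for_any_seed(self, seed):
        design = DesignConfig()
        sched = make_schedule(design, 1, np.random.default_rng(seed))
        sched.validate(design)  # raises on any violation
        # strict alternation with random first valence
        cs = [t.cs for t in sched.learning_trials]
        assert all(a != b for a, b in zip(cs, cs[1:]))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_learning_phase_duration_bounds(self, seed):
        design = DesignConfig()
        sched = make_schedule(design, 1, np.random.default_rng(seed))
        learn = sched.learning_trials
        span = learn[-1].offset - learn[0].onset
        assert 12 * 6 + 11 * 10 <= span <= 12 * 6 + 11 * 16


# ---------------------------------------------------------------------------
# SCR kernel
# ---------------------------------------------------------------------------

class TestKernel:
    def test_zero_before_and_at_latency(self):
        k = SCRKernel(amplitude=1.0)
        assert scr_kernel_eval(k, 0.5) == 0.0
        assert scr_kernel_eval(k, k.latency) == 0.0

    def test_peak_normalisation_on_dense_grid(self):
        k = SCRKernel(amplitude=1.0)
        t = np.linspace(0, 30, 300_001)
        assert abs(scr_kernel_eval(k, t).max() - 1.0) < 1e-6

    def test_peak_time_closed_form_matches_grid(self):
        k = SCRKernel(amplitude=2.0, tau_rise=0.5, tau_decay=3.0, latency=0.8)
        t = np.linspace(0, 30, 300_001)
        vals = scr_kernel_eval(k, t)
        assert abs(t[np.argmax(vals)] - k.peak_time) < 1e-3

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError, match="tau_decay > tau_rise"):
            SCRKernel(tau_rise=2.5, tau_decay=0.75)


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------

class TestDemonstratorTrace:
    def test_all_sources_off_gives_zero_trace(self, schedule):
        kerns = {k: SCRKernel(amplitude=0.0) for k in default_kernels()}
        cpl = quiet_coupling()
        trace, _ = synth_demonstrator_trace(schedule, kerns, cpl,
                                            np.random.default_rng(0))
        assert np.all(trace.values == 0.0)

    def test_single_shock_peaks_at_analytic_time(self, rng, kernels):
        design = DesignConfig(n_cs_each_learning=1, n_shocked_csplus=1)
        sched = make_schedule(design, 1, rng)
        kerns = {k: SCRKernel(amplitude=0.0) for k in kernels}
        kerns["shock"] = SCRKernel(amplitude=1.0)
        cpl = quiet_coupling(response_prob=1.0)
        trace, events = synth_demonstrator_trace(sched, kerns, cpl,
                                                 np.random.default_rng(1),
                                                 sample_rate=32.0)
        shock_time = next(t.shock_time for t in sched.learning_trials if t.shock)
        expected_peak = shock_time + kerns["shock"].peak_time
        observed_peak = np.argmax(trace.values) / trace.fs
        assert abs(observed_peak - expected_peak) <= 1.0 / trace.fs

    def test_deterministic_under_fixed_seed(self, schedule, kernels):
        cpl = CouplingConfig()
        a, _ = synth_demonstrator_trace(schedule, kernels, cpl,
                                        np.random.default_rng(7))
        b, _ = synth_demonstrator_trace(schedule, kernels, cpl,
                                        np.random.default_rng(7))
        assert np.array_equal(a.values, b.values)

    def test_empty_phase_rejected(self, schedule, kernels):
        schedule.trials = [t for t in schedule.trials if t.phase == "testing"]
        with pytest.raises(ValueError, match="no learning trials"):
            synth_demonstrator_trace(schedule, kernels, CouplingConfig(),
                                     np.random.default_rng(0))


class TestObserverTrace:
    def test_full_coupling_zero_lag_copies_demonstrator(self, schedule, kernels):
        cpl = quiet_coupling(kappa=1.0)
        rng = np.random.default_rng(0)
        demo, events = synth_demonstrator_trace(schedule, kernels, cpl, rng)
        obs = synth_observer_trace(events, schedule, cpl, kernels, rng,
                                   demo_drift=demo.meta.get("drift"))
        assert np.allclose(demo.values, obs.values)

    def test_uncoupled_pairs_are_nearly_uncorrelated(self):
        """Mean lag-0 correlation between kappa=0 dyad members stays small."""
        rs = []
        for seed in range(5):
            design = DesignConfig(n_dyads=20, n_blocks=1, sample_rate=8,
                                  seed=300 + seed)
            ds = generate_dataset(design, coupling_sampler=lambda rng: 0.0,
                                  seed=300 + seed)
            for dyad in ds:
                rec = dyad.blocks[0]
                d = zscore(rec.trace("demonstrator", "learning")).values
                o = zscore(rec.trace("observer", "learning")).values
                n = min(len(d), len(o))
                rs.append(np.corrcoef(d[:n], o[:n])[0, 1])
        assert abs(np.mean(rs)) < 0.2

    def test_coupling_increases_correlation_monotonically(self):
        """Mean lag-0 correlation rises strictly across the kappa grid."""
        means = []
        for i, kappa in enumerate([0.0, 0.25, 0.5, 0.75, 1.0]):
            design = DesignConfig(n_dyads=50, n_blocks=1, sample_rate=8,
                                  seed=400 + i)
            ds = generate_dataset(design, seed=400 + i,
                                  coupling_sampler=lambda rng: kappa)
            rs = []
            for dyad in ds:
                rec = dyad.blocks[0]
                d = zscore(rec.trace("demonstrator", "learning")).values
                o = zscore(rec.trace("observer", "learning")).values
                n = min(len(d), len(o))
                rs.append(np.corrcoef(d[:n], o[:n])[0, 1])
            means.append(np.mean(rs))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_no_link_gives_symmetric_test_responses(self, design8):
        """learning_gain=0, no extinction, no base differentiation →
        generated CS+ and CS− testing amplitudes agree on average."""
        cpl = CouplingConfig(learning_gain=0.0, extinction_rate=0.0,
                             beta_cs_base=0.0)
        ds = generate_dataset(DesignConfig(n_dyads=30, n_blocks=1,
                                           sample_rate=8, seed=5),
                              seed=5, coupling=cpl)
        diffs = []
        for dyad in ds:
            rec = dyad.blocks[0]
            tab = score_phase(rec.trace("observer", "testing"), rec.schedule,
                              phase="testing")
            diffs.append(tab.loc[tab.cs_code > 0, "amplitude_raw"].mean()
                         - tab.loc[tab.cs_code < 0, "amplitude_raw"].mean())
        assert abs(np.mean(diffs)) < 0.05

    def test_kappa_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            CouplingConfig(kappa=1.5)

    def test_learning_gain_recovered_from_generated_amplitudes(self):
        """Regressing per-dyad testing CS differentiation on kappa returns
        the generative learning_gain within two standard errors."""
        import statsmodels.api as sm

        cpl = CouplingConfig(learning_gain=0.5, extinction_rate=0.0,
                             beta_cs_base=0.0)
        ds = generate_dataset(DesignConfig(n_dyads=69, n_blocks=1,
                                           sample_rate=8, seed=11),
                              seed=11, coupling=cpl)
        kappas, diffs = [], []
        for dyad in ds:
            rec = dyad.blocks[0]
            tab = score_phase(rec.trace("observer", "testing"), rec.schedule,
                              phase="testing")
            kappas.append(dyad.kappa)
            diffs.append(tab.loc[tab.cs_code > 0, "amplitude_raw"].mean()
                         - tab.loc[tab.cs_code < 0, "amplitude_raw"].mean())
        fit = sm.OLS(diffs, sm.add_constant(np.asarray(kappas))).fit()
        assert abs(fit.params[1] - 0.5) < 2 * fit.bse[1]


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

class TestDataset:
    def test_default_design_yields_276_dyad_block_phases(self):
        ds = generate_dataset(DesignConfig(n_dyads=69, n_blocks=4,
                                           sample_rate=8, seed=1), seed=1)
        pairs = [(d.dyad_id, b.block) for d in ds for b in d.blocks]
        assert len(pairs) == 276
        rec = ds.dyads[0].blocks[0]
        assert set(rec.traces) == {(r, p) for r in ("demonstrator", "observer")
                                   for p in ("learning", "testing")}

    def test_identical_seed_identical_dataset(self):
        design = DesignConfig(n_dyads=3, n_blocks=1, sample_rate=8, seed=9)
        a = generate_dataset(design, seed=9)
        b = generate_dataset(design, seed=9)
        for da, db in zip(a, b):
            assert da.kappa == db.kappa
            for ra, rb in zip(da.blocks, db.blocks):
                for key in ra.traces:
                    assert np.array_equal(ra.traces[key].values,
                                          rb.traces[key].values)

    def test_constant_sampler_fixes_ground_truth(self):
        ds = generate_dataset(DesignConfig(n_dyads=3, n_blocks=1,
                                           sample_rate=8, seed=2),
                              coupling_sampler=lambda rng: 0.5, seed=2)
        assert all(d.kappa == 0.5 for d in ds)
        assert np.all(ds.ground_truth()["kappa"].to_numpy() == 0.5)

    def test_single_dyad_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_dataset(DesignConfig(n_dyads=1, seed=0))

    def test_role_reversal_metadata(self, small_dataset):
        assert small_dataset.observer_person(1) == "A"
        assert small_dataset.observer_person(2) == "B"
        assert small_dataset.observer_id("d1", 2) == "d1-B"

    def test_traces_cover_schedule_span(self, small_dataset):
        for dyad in small_dataset:
            for rec in dyad.blocks:
                for phase in ("learning", "testing"):
                    span = max(t.offset for t in rec.schedule.phase_trials(phase))
                    for role in ("demonstrator", "observer"):
                        assert rec.trace(role, phase).duration >= span
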