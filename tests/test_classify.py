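"""Correlation machinery, time-locking, the chance threshold, and the
classification decision rule."""

import numpy as np
import pytest

from spinecalc import classify
from spinecalc.classify import (above_chance_threshold_pct,
                                behavioral_regressor_correlation,
                                classify_spine, false_positive_threshold,
                                network_correlation_batch, network_signal,
                                sparse_noise_responsive, stim_correlation,
                                timelocked_pct)
from spinecalc.synthgen import transient_kernel

FS = 15.0


class TestStimCorrelation:
    def test_perfect_correlation(self, rng):
        y = (rng.random(2000) > 0.7).astype(float)
        r, p = stim_correlation(y.copy(), y)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_constant_track_rejected(self, rng):
        with pytest.raises(ValueError, match="stimulus"):
            stim_correlation(rng.normal(0, 1, 100), np.ones(100))

    def test_independent_white_noise_calibration(self, rng):
        # at p < 0.05 the false-positive rate is ~5% over replicates
        hits = 0
        n_rep = 400
        y = np.zeros(600)
        y[::12] = 1.0
        for _ in range(n_rep):
            x = rng.normal(0, 1, 600)
            _r, p = stim_correlation(x, y)
            hits += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert hits / n_rep == pytest.approx(0.05, abs=4 * se)

    def test_parametric_matches_scipy(self, rng):
        from scipy import stats

        x = rng.normal(0, 1, 500)
        y = (rng.random(500) > 0.5).astype(float)
        r, p = stim_correlation(x, y, method="parametric")
        r2, p2 = stats.pearsonr(x, y)
        assert (r, p) == pytest.approx((r2, p2))

    def test_autocorrelated_trace_keeps_level_with_circular_null(self, rng):
        # kernel-smoothed traces inflate the parametric false-positive rate;
        # the circular-shift null stays near the nominal level
        kern = transient_kernel(FS)
        y = np.zeros(3600)
        for k in range(0, 3600, 90):
            y[k:k + 45] = 1.0
        hits_circ = hits_par = 0
        n_rep = 150
        for _ in range(n_rep):
            spikes = (rng.random(3600) < 0.017).astype(float)
            x = np.convolve(spikes, kern)[:3600] + rng.normal(0, 0.03, 3600)
            _r, p = stim_correlation(x, y)
            hits_circ += (p < 0.05)
            _r, p2 = stim_correlation(x, y, method="parametric")
            hits_par += (p2 < 0.05)
        assert hits_circ / n_rep < 0.12
        assert hits_par / n_rep > 0.25  # anti-conservative


class TestNetworkSignal:
    def test_identical_traces_reference_equals_trace(self, rng):
        x = rng.normal(0, 1, 300)
        traces = np.tile(x, (5, 1))
        ref = network_signal(traces, 2)
        assert np.allclose(ref, x)

    def test_leave_one_out_excludes_self(self, rng):
        traces = rng.normal(0, 1, (4, 200))
        ref = network_signal(traces, 1)
        expected = traces[[0, 2, 3]].mean(axis=0)
        assert np.allclose(ref, expected)

    def test_two_spines_rejected(self, rng):
        with pytest.raises(ValueError, match="3"):
            network_signal(rng.normal(0, 1, (2, 100)), 0)

    def test_batch_matches_pairwise(self, rng):
        kern = transient_kernel(FS)
        traces = np.stack([
            np.convolve((rng.random(1200) < 0.02).astype(float), kern)[:1200]
            for _ in range(6)])
        r, _p = network_correlation_batch(traces)
        for i in range(6):
            ri, _ = classify.network_correlation(traces[i],
                                                 network_signal(traces, i))
            assert r[i] == pytest.approx(ri, abs=1e-10)

    def test_negative_correlation_not_significant_positive(self, rng):
        x = rng.normal(0, 1, 500)
        r, p = classify.network_correlation(-x, x)
        assert r == pytest.approx(-1.0)
        assert not classify.significant_positive(r, p)


class TestTimelocking:
    def test_event_at_every_onset_is_100pct(self):
        pres = np.arange(0.0, 100.0, 5.0)
        assert timelocked_pct(pres + 0.2, pres) == 100.0

    def test_no_events_is_0pct(self):
        assert timelocked_pct(np.array([]), np.arange(0, 50, 5.0)) == 0.0

    def test_window_is_half_second(self):
        pres = np.array([10.0])
        assert timelocked_pct(np.array([10.49]), pres) == 100.0
        assert timelocked_pct(np.array([10.51]), pres) == 0.0

    def test_poisson_events_match_analytic_rate(self, rng):
        lam = 0.113
        analytic = 1 - np.exp(-lam * 0.5)
        vals = []
        pres = np.arange(1.0, 3600.0, 6.0)
        for _ in range(30):
            n = rng.poisson(lam * 3600)
            ev = np.sort(rng.uniform(0, 3600, n))
            vals.append(timelocked_pct(ev, pres) / 100)
        se = np.sqrt(analytic * (1 - analytic) / (30 * pres.size))
        assert np.mean(vals) == pytest.approx(analytic, abs=3 * se)

    def test_requires_presentations(self):
        with pytest.raises(ValueError):
            timelocked_pct(np.array([1.0]), np.array([]))


class TestFalsePositiveThreshold:
    def test_silent_spine_zero(self):
        dummy = np.arange(0, 100, 5.0)
        assert false_positive_threshold(np.array([]), dummy) == 0.0

    def test_empty_dummy_rejected(self):
        with pytest.raises(ValueError, match="dummy"):
            false_positive_threshold(np.array([1.0]), np.array([]))

    def test_above_chance_threshold_semantics(self):
        # with 80 presentations and a 5.5% null, the critical percentage
        # equals (c-1)/80 where c is the smallest count with
        # P(Bin(80, 0.055) >= c) <= alpha
        from scipy import stats

        thr = above_chance_threshold_pct(5.5, 80, alpha=0.01)
        c = int(thr / 100 * 80) + 1
        assert stats.binom.sf(c - 1, 80, 0.055) <= 0.01
        assert stats.binom.sf(c - 2, 80, 0.055) > 0.01

    def test_population_floor_applies(self):
        lone = above_chance_threshold_pct(0.0, 80, population_fp_pct=5.5)
        assert lone == above_chance_threshold_pct(5.5, 80)
        assert lone > 0


class TestSparseNoise:
    def test_flat_trace_has_no_responsive_trials(self, rng):
        x = rng.normal(0, 0.02, 4000)
        onsets = 20.0 + np.arange(240) * 0.25
        trials, dec = sparse_noise_responsive(x, onsets, FS)
        assert trials.sum() <= 1
        assert not dec

    def test_injected_responses_are_flagged(self, rng):
        # transients on 30 of 240 trials, amplitude >= 5x noise
        kern = transient_kernel(FS)
        onsets = 20.0 + np.arange(240) * 0.25
        hit = rng.choice(240, 30, replace=False)
        x = rng.normal(0, 0.02, 4000)
        for h in hit:
            i = int(round(onsets[h] * FS))
            x[i:i + kern.size] += 0.5 * kern[:min(kern.size, 4000 - i)]
        trials, dec = sparse_noise_responsive(x, onsets, FS)
        assert dec
        assert trials[hit].sum() >= 28
        others = np.setdiff1d(np.arange(240), hit)
        assert trials[others].mean() < 0.02  # near the null rate

    def test_insufficient_trials_rejected(self, rng):
        with pytest.raises(ValueError, match="insufficient"):
            sparse_noise_responsive(rng.normal(0, 1, 1000),
                                    np.arange(30) * 0.25 + 5, FS)

    def test_empirical_null_raises_the_bar(self, rng):
        # a trace with frequent spontaneous transients: the dummy-trial null
        # absorbs them, so the spine is not called responsive
        kern = transient_kernel(FS)
        spikes = (rng.random(9000) < 0.02).astype(float) * 0.4
        x = np.convolve(spikes, kern)[:9000] + rng.normal(0, 0.02, 9000)
        onsets = 20.0 + np.arange(240) * 0.25
        nulls = 320.0 + np.arange(240) * 0.25
        _t, dec = sparse_noise_responsive(x, onsets, FS, null_onsets_s=nulls)
        assert not dec


class TestDecisionRule:
    BASE = {"r_net": 0.3, "p_net": 0.001, "r_stim_vis": 0.0,
            "p_stim_vis": 0.8, "timelocked_vis_pct": 2.0,
            "fp_threshold_vis_pct": 10.0}

    def test_network_correlated(self):
        assert classify_spine(dict(self.BASE)).label == "network_correlated"

    def test_visually_responsive(self):
        d = dict(self.BASE, r_stim_vis=0.2, p_stim_vis=0.001,
                 timelocked_vis_pct=30.0)
        assert classify_spine(d).label == "visually_responsive"

    def test_sparse_noise_overrides_gratings(self):
        d = dict(self.BASE, sparse_noise_responsive=True)
        assert classify_spine(d).label == "visually_responsive"

    def test_unclassified_when_nothing_significant(self):
        d = dict(self.BASE, r_net=0.01, p_net=0.4)
        assert classify_spine(d).label == "unclassified"

    def test_excluded_when_locked_above_chance_without_correlation(self):
        d = dict(self.BASE, timelocked_vis_pct=12.0)
        assert classify_spine(d).label == "excluded"

    def test_timelocked_gate_requires_both_conditions(self):
        # significant correlation but chance-level locking -> not visual
        d = dict(self.BASE, r_stim_vis=0.2, p_stim_vis=0.001)
        assert classify_spine(d).label == "network_correlated"

    def test_rsc_auditory(self):
        d = dict(self.BASE, r_stim_aud=0.25, p_stim_aud=0.001,
                 timelocked_aud_pct=60.0, fp_threshold_aud_pct=12.0)
        assert classify_spine(d, region="RSC").label == "auditory_responsive"

    def test_missing_fp_threshold_raises(self):
        d = {"r_stim_vis": 0.3, "p_stim_vis": 0.001, "r_net": 0.0,
             "p_net": 1.0}
        with pytest.raises(ValueError, match="threshold"):
            classify_spine(d)


class TestBehavioralHook:
    def test_self_correlation(self, rng):
        x = rng.normal(0, 1, 400)
        r, _p = behavioral_regressor_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_constant_regressor_rejected(self, rng):
        with pytest.raises(ValueError):
            behavioral_regressor_correlation(rng.normal(0, 1, 100),
                                             np.full(100, 2.0))

    def test_independent_regressor_significance_near_nominal(self, rng):
        hits = 0
        for _ in range(200):
            x = rng.normal(0, 1, 500)
            reg = rng.normal(0, 1, 500)
            _r, p = behavioral_regressor_correlation(x, reg)
            hits += p < 0.05
        assert hits / 200 == pytest.approx(0.05, abs=0.05)
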