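"""Generator ground truth: event statistics, rendering, deprivation."""

import numpy as np
import pytest

from spinecalc.config import Epoch, GeneratorConfig, build_config
from spinecalc.classify import timelocked_pct
from spinecalc.synthgen import (assign_population, generate_session,
                                simulate_events, transient_kernel)
from spinecalc.schedule import make_schedule


def _dark_cfg(n=300, seed=9, **kw):
    return GeneratorConfig(
        seed=seed, n_spines=n, region="V1",
        class_mixture={"visual": 0.0, "auditory": 0.0, "network_only": 0.0,
                       "unclassified": 1.0},
        session_layout=[Epoch("dark", 360.0)], timepoints=[-1.0], **kw)


class TestPopulation:
    def test_class_counts_match_mixture(self):
        truth = assign_population(build_config(None, "V1-baseline",
                                               {"n_spines": 200}))
        counts = truth.spines.true_class.value_counts()
        assert counts["visual"] == 48
        assert counts["network_only"] == 130
        assert counts["unclassified"] == 22

    def test_branch_sizes_in_range(self):
        truth = assign_population(build_config(None, "V1-baseline",
                                               {"n_spines": 300}))
        sizes = truth.spines.groupby("branch_id").size()
        assert sizes.iloc[:-1].between(8, 15).all()
        assert sizes.iloc[-1] >= 2

    def test_positions_contiguous_within_branch(self):
        truth = assign_population(build_config(None, "V1-baseline",
                                               {"n_spines": 100}))
        for _b, g in truth.spines.groupby("branch_id"):
            assert sorted(g.position_index) == list(range(len(g)))

    def test_alpha_and_f0_ranges(self):
        truth = assign_population(build_config(None, "V1-baseline",
                                               {"n_spines": 100}))
        assert truth.spines.alpha_true.between(0.2, 0.8).all()
        assert truth.spines.f0_spine.between(1.5, 3.0).all()


class TestSimulateEvents:
    def test_background_count_matches_poisson_mean(self):
        # 0.113 Hz x 360 s = 40.68 expected events per spine
        cfg = _dark_cfg(n=1000)
        truth = assign_population(cfg)
        ev = simulate_events(cfg, make_schedule(cfg, 0), truth, -1.0)
        counts = [t.size for t in ev.spine_times]
        expect = 0.113 * 360
        se = np.sqrt(expect / len(counts))
        assert np.mean(counts) == pytest.approx(expect, abs=3 * se)

    def test_full_coupling_inherits_every_latent_event(self):
        cfg = build_config(None, "V1-baseline",
                           {"n_spines": 50, "coupling_weight": 1.0})
        truth = assign_population(cfg)
        ev = simulate_events(cfg, make_schedule(cfg, 0), truth, -24.0)
        i = int(np.flatnonzero(truth.spines.true_class == "network_only")[0])
        inherited = ev.spine_times[i][ev.spine_origin[i] == "l"]
        assert np.allclose(np.sort(inherited), ev.latent_times)

    def test_enucleation_removes_visual_evoked_keeps_background(self):
        cfg = build_config(None, "V1-enucleation",
                           {"n_spines": 80, "seed": 3})
        # disable silencing so every visual spine is observable
        cfg.deprivation.inactivation_prob_by_class = {}
        truth = assign_population(cfg)
        ev48 = simulate_events(cfg, make_schedule(cfg, 4), truth, 48.0)
        vis = np.flatnonzero(truth.spines.true_class == "visual")
        for i in vis:
            assert not np.any(ev48.spine_origin[i] == "e")
            assert np.any(ev48.spine_origin[i] == "b")

    def test_silenced_spines_have_zero_events(self):
        cfg = build_config(None, "V1-enucleation", {"n_spines": 300, "seed": 3})
        truth = assign_population(cfg)
        ev = simulate_events(cfg, make_schedule(cfg, 2), truth, 12.0)
        sil = truth.is_silenced(12.0).to_numpy()
        assert sil.any()
        for i in np.flatnonzero(sil):
            assert ev.spine_times[i].size == 0

    def test_tnf_blockade_prevents_amplitude_scaling(self):
        base = {"n_spines": 200, "seed": 4}
        cfg_dep = build_config(None, "V1-enucleation", dict(base))
        cfg_tnf = build_config(None, "V1-enucleation-TNF", dict(base))
        for cfg in (cfg_dep, cfg_tnf):
            cfg.deprivation.inactivation_prob_by_class = {}
        t_dep = assign_population(cfg_dep)
        t_tnf = assign_population(cfg_tnf)
        net = np.flatnonzero(t_dep.spines.true_class == "network_only")
        ev_dep = simulate_events(cfg_dep, make_schedule(cfg_dep, 4), t_dep, 48.0)
        ev_tnf = simulate_events(cfg_tnf, make_schedule(cfg_tnf, 4), t_tnf, 48.0)
        m_dep = np.mean([ev_dep.spine_amps[i].mean() for i in net])
        m_tnf = np.mean([ev_tnf.spine_amps[i].mean() for i in net])
        # same seeds, same draws; only the scaling differs (x1.3 mean)
        assert m_dep / m_tnf == pytest.approx(1.3, abs=0.08)

    def test_analytic_false_positive_rate_on_true_events(self):
        # fraction of dummy windows containing a background event onset
        # converges to 1 - exp(-lambda * w)
        cfg = _dark_cfg(n=1000)
        truth = assign_population(cfg)
        ev = simulate_events(cfg, make_schedule(cfg, 0), truth, -1.0)
        dummy = np.arange(2.0, 358.0, 4.45)[:80]
        fps = [timelocked_pct(ev.spine_times[i], dummy) / 100.0
               for i in range(cfg.n_spines)]
        analytic = 1 - np.exp(-0.113 * 0.5)
        se = np.sqrt(analytic * (1 - analytic) / (80 * cfg.n_spines))
        assert np.mean(fps) == pytest.approx(analytic, abs=3 * se)


class TestRenderTraces:
    def test_bit_identical_for_identical_seeds(self):
        cfg = build_config(None, "V1-baseline", {"n_spines": 20, "seed": 8})
        t1 = assign_population(cfg)
        t2 = assign_population(cfg)
        a = generate_session(cfg, t1, -24.0)[0]
        b = generate_session(cfg, t2, -24.0)[0]
        assert np.array_equal(a.spine_traces, b.spine_traces)
        assert np.array_equal(a.dend_traces, b.dend_traces)

    def test_kernel_peak_is_unit(self):
        # sampled peak within 2% of the continuous-time unit peak
        kern = transient_kernel(15.0)
        assert kern.max() == pytest.approx(1.0, abs=0.02)

    def test_single_event_peak_matches_amplitude(self):
        cfg = _dark_cfg(n=5, noise_sd=0.0)
        cfg.drift.amplitude = 0.0
        cfg.background_rate = 1e-9
        cfg.dend_background_rate = 1e-9
        cfg.latent_rate = 1e-9
        truth = assign_population(cfg)
        ev = simulate_events(cfg, make_schedule(cfg, 0), truth, -1.0)
        ev.spine_times[0] = np.array([100.0])
        ev.spine_amps[0] = np.array([0.5])
        ev.spine_origin[0] = np.array(["b"])
        from spinecalc.synthgen import render_traces

        tm = render_traces(cfg, truth, ev)
        f0 = truth.spines.f0_spine.iloc[0]
        sig = tm.spine_traces[0] / f0 - 1.0
        assert sig.max() == pytest.approx(0.5, rel=0.02)

    def test_zero_alpha_decorrelates_spine_from_dendrite(self):
        cfg = _dark_cfg(n=30, seed=21, alpha_range=(0.0, 1e-12))
        truth = assign_population(cfg)
        tm, *_ = generate_session(cfg, truth, -1.0)
        rs = [abs(np.corrcoef(tm.spine_traces[i], tm.dend_traces[i])[0, 1])
              for i in range(10)]
        assert np.median(rs) < 0.05

    def test_traces_positive(self):
        cfg = build_config(None, "V1-baseline", {"n_spines": 30, "seed": 2})
        truth = assign_population(cfg)
        tm, *_ = generate_session(cfg, truth, -24.0)
        assert tm.spine_traces.min() > 0
        assert tm.dend_traces.min() > 0
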