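"""Longitudinal table, normalised changes, clustering, OSI, coupling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spinecalc.population import (align_longitudinal, add_normalized_changes,
                                  clustering_curve, freq_amp_coupling,
                                  global_dendrite_analysis, inactive_fraction,
                                  normalized_pct_change, osi)


def _metrics(rows):
    return pd.DataFrame(rows, columns=["spine_id", "timepoint_hr",
                                       "mean_amplitude", "frequency",
                                       "integral", "active"])


class TestAlignLongitudinal:
    def test_persistence_and_inclusion(self):
        rows = []
        for tp in (-24.0, -1.0, 12.0):
            rows += [("a", tp, 1.0, 0.1, 1.0, True),
                     ("b", tp, 1.0, 0.1, 1.0, tp == -24.0),
                     ("c", tp, np.nan, 0.0, 0.0, False)]
        tab = align_longitudinal(_metrics(rows))
        assert set(tab.spine_id) == {"a", "b"}  # c never active -> dropped
        assert tab[tab.spine_id == "a"].persistent.all()
        assert not tab[tab.spine_id == "b"].persistent.any()

    def test_labels_held_fixed_from_baseline(self):
        rows = [("a", tp, 1.0, 0.1, 1.0, True) for tp in (-1.0, 12.0)]
        tab = align_longitudinal(_metrics(rows),
                                 pd.Series({"a": "network_correlated"}))
        assert (tab.label == "network_correlated").all()

    def test_missing_timepoint_rejected(self):
        rows = [("a", -1.0, 1, 1, 1, True), ("a", 12.0, 1, 1, 1, True),
                ("b", -1.0, 1, 1, 1, True)]
        with pytest.raises(ValueError, match="timepoint"):
            align_longitudinal(_metrics(rows))


class TestNormalizedChange:
    def test_constant_series_is_zero_everywhere(self):
        tps = np.array([-24.0, -1.0, 12.0, 48.0])
        out = normalized_pct_change(np.full(4, 2.5), tps, (-24.0, -1.0))
        assert np.allclose(out, 0.0)

    def test_thirty_percent_increase(self):
        out = normalized_pct_change(np.array([1.0, 1.0, 1.3]),
                                    np.array([-24.0, -1.0, 48.0]),
                                    (-24.0, -1.0))
        assert out.loc[48.0] == pytest.approx(30.0)

    def test_baseline_mean_maps_to_zero_exactly(self, rng):
        # normalisation identity: the mean over baseline timepoints is 0
        for _ in range(50):
            v = rng.uniform(0.5, 2.0, 4)
            out = normalized_pct_change(v, np.array([-24.0, -1.0, 12.0, 48.0]),
                                        (-24.0, -1.0))
            assert out.loc[[-24.0, -1.0]].mean() == pytest.approx(0.0, abs=1e-12)

    def test_missing_baseline_flags_spine(self):
        out = normalized_pct_change(np.array([np.nan, 1.0, 1.3]),
                                    np.array([-24.0, -1.0, 48.0]),
                                    (-24.0, -1.0))
        assert out.isna().all()


class TestInactiveFraction:
    def test_all_active_zero(self):
        rows = [(f"s{i}", -1.0, 1, 1, 1, True) for i in range(5)]
        tab = align_longitudinal(_metrics(rows))
        assert inactive_fraction(tab, -1.0) == 0.0

    def test_counts_inactive_at_timepoint(self):
        rows = []
        for i in range(10):
            rows += [(f"s{i}", -1.0, 1, 1, 1, True),
                     (f"s{i}", 12.0, 1, 1, 1, i >= 2)]
        tab = align_longitudinal(_metrics(rows))
        assert inactive_fraction(tab, 12.0) == pytest.approx(20.0)


class TestClustering:
    def test_uniform_labels_match_everywhere(self):
        b = np.zeros(10, dtype=int)
        curve = clustering_curve(b, np.array(["x"] * 10), np.arange(10),
                                 n_shuffles=50, seed=0)
        assert np.allclose(curve.observed, 1.0)

    def test_strict_alternation(self):
        labels = np.array(["a", "b"] * 5)
        curve = clustering_curve(np.zeros(10, int), labels, np.arange(10),
                                 n_shuffles=50, seed=0, max_distance=2)
        assert curve.observed[0] == 0.0
        assert curve.observed[1] == 1.0

    def test_independent_labels_match_sum_of_squares(self, rng):
        # mixture (0.24, 0.65, 0.11): sum p^2 = 0.4922
        p = np.array([0.24, 0.65, 0.11])
        labels = rng.choice(np.array(["v", "n", "u"]), size=3000, p=p)
        branch = np.repeat(np.arange(300), 10)
        pos = np.tile(np.arange(10), 300)
        curve = clustering_curve(branch, labels, pos, n_shuffles=200, seed=1)
        expect = float((p ** 2).sum())
        # ~2700 ordered-pair sites at distance 1; 3 SE band on the mean
        se = np.sqrt(expect * (1 - expect) / 2700)
        assert np.nanmean(curve.observed) == pytest.approx(expect, abs=3 * se)
        # observed inside the 95% shuffle envelope at nearly every distance
        inside = ((curve.observed >= curve.shuffle_lo - 1e-9)
                  & (curve.observed <= curve.shuffle_hi + 1e-9))
        assert inside.sum() >= len(inside) - 2

    def test_shuffle_mean_matches_exchangeability_oracle(self, rng):
        # per-branch permutation: E[match at any distance] equals the mean
        # over branches of P(two distinct positions share a label)
        labels = rng.choice(np.array(["a", "b", "c"]), size=120,
                            p=[0.5, 0.3, 0.2])
        branch = np.repeat(np.arange(12), 10)
        pos = np.tile(np.arange(10), 12)
        curve = clustering_curve(branch, labels, pos, n_shuffles=800, seed=4)
        oracle = []
        for b in range(12):
            lab = labels[branch == b]
            s = lab.size
            counts = pd.Series(lab).value_counts().to_numpy()
            oracle.append((counts * (counts - 1)).sum() / (s * (s - 1)))
        assert np.nanmean(curve.shuffle_mean) == pytest.approx(
            np.mean(oracle), abs=0.02)

    def test_brute_force_enumeration_on_small_branch(self):
        # exhaustive check of the match probability on one 6-spine branch
        labels = np.array(["a", "a", "b", "b", "b", "c"])
        curve = clustering_curve(np.zeros(6, int), labels, np.arange(6),
                                 n_shuffles=2000, seed=3, max_distance=2)
        # shuffle mean at distance n = expected match over all permutations;
        # by exchangeability = P(two distinct positions share a label)
        pairs = list(itertools.combinations(range(6), 2))
        p_match = np.mean([labels[i] == labels[j] for i, j in pairs])
        assert curve.shuffle_mean[0] == pytest.approx(p_match, abs=0.03)
        assert curve.shuffle_mean[1] == pytest.approx(p_match, abs=0.03)

    def test_shuffle_preserves_label_multiset(self):
        # a clustered 3a+7b branch: the shuffle mean sits at the
        # exchangeable value (3*2 + 7*6)/90 regardless of distance
        labels = np.array(["a"] * 3 + ["b"] * 7)
        curve = clustering_curve(np.zeros(10, int), labels, np.arange(10),
                                 n_shuffles=2000, seed=0, max_distance=3)
        assert np.allclose(curve.shuffle_mean, 48 / 90, atol=0.03)

    def test_requires_branch_with_two_spines(self):
        with pytest.raises(ValueError, match="branch"):
            clustering_curve(np.arange(3), np.array(["a", "b", "c"]),
                             np.zeros(3), n_shuffles=10, seed=0)


class TestFreqAmpCoupling:
    def _table(self, freq12, amp48):
        rows = []
        for i, (f, a) in enumerate(zip(freq12, amp48)):
            rows += [(f"s{i}", -24.0, 1.0, 1.0, 1.0, True),
                     (f"s{i}", -1.0, 1.0, 1.0, 1.0, True),
                     (f"s{i}", 12.0, 1.0, f, 1.0, True),
                     (f"s{i}", 48.0, a, 1.0, 1.0, True)]
        return align_longitudinal(_metrics(rows))

    def test_identical_changes_give_unit_correlation(self, rng):
        v = rng.uniform(1.1, 2.0, 12)
        res = freq_amp_coupling(self._table(v, v), 12.0, 48.0, (-24.0, -1.0))
        assert res["r"] == pytest.approx(1.0, abs=1e-9)

    def test_antisymmetric_changes_give_minus_one(self, rng):
        d = rng.uniform(0.1, 0.5, 10)
        res = freq_amp_coupling(self._table(1 + d, 1 - d), 12.0, 48.0,
                                (-24.0, -1.0))
        assert res["r"] == pytest.approx(-1.0, abs=1e-9)

    def test_independent_changes_uncorrelated(self, rng):
        ps = []
        for _ in range(25):
            res = freq_amp_coupling(
                self._table(rng.uniform(0.8, 1.2, 40),
                            rng.uniform(0.8, 1.2, 40)),
                12.0, 48.0, (-24.0, -1.0))
            ps.append(res["p"])
        assert np.mean(np.array(ps) < 0.05) < 0.2
        assert res["method"] in ("pearson", "spearman")


class TestOsi:
    def test_equal_responses_zero(self):
        assert osi(np.ones(8)) == 0.0

    def test_single_orientation_one(self):
        r = np.zeros(8)
        r[1] = 2.0
        r[5] = 2.0  # opposite direction, same orientation
        assert osi(r) == 1.0

    def test_pref_two_orth_one_third(self):
        r = np.array([2.0, 1.0, 1.0, 1.0, 2.0, 1.0, 1.0, 1.0])
        assert osi(r) == pytest.approx(1.0 / 3.0)

    def test_scale_invariance(self, rng):
        r = rng.uniform(0.1, 2.0, 8)
        assert osi(3.7 * r) == pytest.approx(osi(r))

    def test_all_zero_undefined(self):
        assert np.isnan(osi(np.zeros(8)))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            osi(np.array([1, -1, 1, 1, 1, 1, 1, 1.0]))


class TestGlobalDendrite:
    def test_constructed_branch_changes_correlate_only_for_matching_class(self, rng):
        n_branch = 30
        net_change = rng.normal(30, 10, n_branch)
        rows = []
        for b in range(n_branch):
            for k in range(4):
                rows.append({"spine_id": f"b{b}k{k}", "branch_id": b,
                             "label": "network_correlated",
                             "mean_amplitude_pct_change":
                                 net_change[b] + rng.normal(0, 2)})
            for k in range(2):
                rows.append({"spine_id": f"b{b}v{k}", "branch_id": b,
                             "label": "visually_responsive",
                             "mean_amplitude_pct_change": rng.normal(0, 10)})
        spine_table = pd.DataFrame(rows)
        branch_changes = pd.Series(net_change, index=np.arange(n_branch))
        out = global_dendrite_analysis(branch_changes, spine_table)
        net = out[out.label == "network_correlated"].iloc[0]
        vis = out[out.label == "visually_responsive"].iloc[0]
        assert net.r > 0.9 and net.p < 0.001
        assert abs(vis.r) < 0.5 and vis.p > 0.01
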