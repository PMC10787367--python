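import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coabnet.data_model import Subgroup
from coabnet.network_diff import (
    EdgeMeta,
    cochran_q,
    edge_universe,
    edges_to_frame,
    genus_of,
    genus_summary,
    heterogeneity_fdr,
    hub_scores,
    iqr_specificity,
)
from coabnet.sparcc import Edge, SubgroupNetwork


class TestCochranQ:
    def test_identical_effects_give_zero(self):
        q, p = cochran_q({"a": 0.5, "b": 0.5, "c": 0.5}, {"a": 10, "b": 12, "c": 14})
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_closed_form_two_subgroups(self):
        """z effects 0 and 1 at n = 30 each: Q = w (z1 - z2)^2 / 2 = 13.5."""
        q, p = cochran_q({"a": math.tanh(0.0), "b": math.tanh(1.0)}, {"a": 30, "b": 30})
        assert q == pytest.approx(13.5, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(13.5, df=1), abs=1e-6)

    def test_relabeling_invariance(self):
        effects = {"x": 0.1, "y": 0.4, "z": -0.2}
        ns = {"x": 10, "y": 20, "z": 15}
        q1, _ = cochran_q(effects, ns)
        q2, _ = cochran_q({"z": -0.2, "x": 0.1, "y": 0.4}, ns)
        assert q1 == pytest.approx(q2)

    def test_small_subgroups_dropped(self):
        # n <= 3 has undefined Fisher-z variance
        assert cochran_q({"a": 0.1, "b": 0.5}, {"a": 3, "b": 30}) is None
        res = cochran_q({"a": 0.1, "b": 0.5, "c": 0.2}, {"a": 3, "b": 30, "c": 30})
        assert res is not None
        q_two, _ = res
        q_ref, _ = cochran_q({"b": 0.5, "c": 0.2}, {"b": 30, "c": 30})
        assert q_two == pytest.approx(q_ref)

    def test_type_one_error_calibration(self):
        """Common true r across k = 3 subgroups: p < 0.05 in ~5% of 500 edges."""
        rng = np.random.default_rng(0)
        n, v = 12, 1.0 / 9.0
        hits = 0
        for _ in range(500):
            true_z = np.arctanh(rng.uniform(-0.5, 0.5))
            z = rng.normal(true_z, np.sqrt(v), size=3)
            _, p = cochran_q({f"g{i}": math.tanh(z[i]) for i in range(3)},
                             {f"g{i}": n for i in range(3)})
            hits += p < 0.05
        # 95% binomial band around 0.05 at 500 draws
        assert 0.05 - 2 * np.sqrt(0.05 * 0.95 / 500) < hits / 500 < 0.05 + 2 * np.sqrt(0.05 * 0.95 / 500)


class TestHeterogeneityFdr:
    def _edges(self, pvals):
        edges = []
        for k, p in enumerate(pvals):
            e = EdgeMeta(edge=(f"a{k}", f"b{k}"), effect_sizes={}, ns={})
            e.p = p
            edges.append(e)
        return edges

    def test_equal_p_is_bh_fixed_point(self):
        edges = self._edges([0.03, 0.03, 0.03])
        # bypass cochran_q by filling p directly through the BH step
        from coabnet.diff_features import bh_fdr

        adj = bh_fdr([e.p for e in edges])
        assert np.allclose(adj, 0.03)

    def test_step_up_by_hand(self):
        from coabnet.diff_features import bh_fdr

        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_fdr_filled_and_monotone(self):
        e1 = EdgeMeta(("a", "b"), {"g1": 0.0, "g2": 0.8}, {"g1": 30, "g2": 30})
        e2 = EdgeMeta(("a", "c"), {"g1": 0.1, "g2": 0.12}, {"g1": 30, "g2": 30})
        out = heterogeneity_fdr([e1, e2])
        assert all(e.fdr >= e.p for e in out)
        assert out[0].heterogeneous  # strong split is detected at FDR 0.05


class TestIqrSpecificity:
    def test_hand_worked_fences(self):
        """Effects (0.10, 0.12, 0.80): Q1=0.11, Q3=0.46, high fence 0.7225."""
        call = iqr_specificity({"CON": 0.10, "RMT": 0.12, "RFT": 0.80})
        assert call.quartiles == (pytest.approx(0.11), pytest.approx(0.46))
        assert call.iqr == pytest.approx(0.35)
        assert call.quartiles[1] + 0.75 * call.iqr == pytest.approx(0.7225)
        assert call.outlier_group == "RFT"
        assert call.direction == "high"

    def test_degenerate_spread_gives_none(self):
        call = iqr_specificity({"CON": 0.3, "RMT": 0.3, "RFT": 0.3})
        assert call.outlier_group is None

    def test_symmetric_two_candidates_give_none(self):
        # fences are +-0.675; both -0.9 and 0.9 fall outside
        call = iqr_specificity({"CON": -0.9, "RMT": 0.0, "RFT": 0.9})
        assert call.outlier_group is None
        assert call.direction == "none"

    def test_missing_effect_size_gives_no_call(self):
        call = iqr_specificity({"CON": 0.1, "RMT": np.nan, "RFT": 0.9})
        assert call.outlier_group is None

    def test_recovery_and_no_false_assignment(self):
        """One group's true r shifted by 0.9: the planted group is found,
        never a wrong one, over effect sizes drawn at n = 50/subgroup."""
        rng = np.random.default_rng(1)
        sd = 1.0 / np.sqrt(47)
        correct = wrong = 0
        reps = 50
        for _ in range(reps):
            z = {"CON": rng.normal(0, sd), "RMT": rng.normal(np.arctanh(0.9), sd),
                 "RFT": rng.normal(0, sd)}
            call = iqr_specificity({g: math.tanh(v) for g, v in z.items()})
            correct += call.outlier_group == "RMT"
            wrong += call.outlier_group not in (None, "RMT")
        assert correct / reps > 0.8
        assert wrong / reps < 0.05


class TestEdgeUniverse:
    def _nets(self):
        sg1 = Subgroup("CON", 15)
        sg2 = Subgroup("RMT", 15)
        feats = ["a", "b", "c", "d"]
        rng = np.random.default_rng(2)
        r1 = pd.DataFrame(np.eye(4), index=feats, columns=feats)
        r2 = r1.copy()
        r1.loc["a", "b"] = r1.loc["b", "a"] = 0.7
        r2.loc["a", "b"] = r2.loc["b", "a"] = 0.1
        n1 = SubgroupNetwork(sg1, [Edge("a", "b", 0.7, 0.005)], 12)
        n2 = SubgroupNetwork(sg2, [], 11)
        return [n1, n2], {sg1.label: r1, sg2.label: r2}

    def test_union_rule_fills_all_subgroups(self):
        nets, rmats = self._nets()
        edges = edge_universe(nets, rmats)
        assert len(edges) == 1
        assert set(edges[0].effect_sizes) == {"CON_d15", "RMT_d15"}
        assert edges[0].effect_sizes["RMT_d15"] == pytest.approx(0.1)
        assert edges[0].ns == {"CON_d15": 12, "RMT_d15": 11}

    def test_identical_edge_sets_deduplicate(self):
        nets, rmats = self._nets()
        nets[1].edges = [Edge("a", "b", 0.1, 0.004)]
        edges = edge_universe(nets, rmats)
        assert len(edges) == 1

    def test_missing_feature_logged_as_nan(self):
        nets, rmats = self._nets()
        rmats["RMT_d15"] = rmats["RMT_d15"].drop(index="a", columns="a")
        edges = edge_universe(nets, rmats)
        assert np.isnan(edges[0].effect_sizes["RMT_d15"])


class TestHubScores:
    def test_star_center_is_the_hub(self):
        edges = [("hub", f"leaf{i}", 1.0) for i in range(5)]
        scores = {h.node: h for h in hub_scores(edges)}
        assert scores["hub"].score == pytest.approx(1.0)
        assert scores["hub"].is_hub
        for i in range(5):
            assert scores[f"leaf{i}"].score == pytest.approx(1 / np.sqrt(5), abs=1e-9)
            assert not scores[f"leaf{i}"].is_hub

    def test_single_edge_both_score_one(self):
        scores = hub_scores([("x", "y", -0.8)])
        assert all(h.score == pytest.approx(1.0) for h in scores)

    def test_order_and_weight_scale_invariance(self):
        rng = np.random.default_rng(3)
        edges = [(f"n{i}", f"n{j}", float(rng.uniform(0.2, 1)))
                 for i in range(6) for j in range(i + 1, 6) if rng.random() < 0.6]
        s1 = {h.node: h.score for h in hub_scores(edges)}
        s2 = {h.node: h.score for h in hub_scores(list(reversed(edges)))}
        s3 = {h.node: h.score for h in hub_scores([(a, b, 10 * w) for a, b, w in edges])}
        assert s1 == pytest.approx(s2)
        assert s1 == pytest.approx(s3)

    def test_every_scored_node_has_an_edge(self):
        scores = hub_scores([("a", "b", 0.5), ("c", "d", 0.9)])
        assert {h.node for h in scores} == {"a", "b", "c", "d"}
        assert hub_scores([]) == []


class TestGenusSummary:
    def test_same_genus_aggregation(self):
        edges = [("s__Bacteroides_fragilis", "s__Bacteroides_uniformis"),
                 ("s__Bacteroides_fragilis", "s__Bacteroides_dorei"),
                 ("s__Bacteroides_dorei", "s__Bacteroides_uniformis")]
        assert genus_summary(edges) == Counter({("Bacteroides", "Bacteroides"): 3})

    def test_cross_genus_unordered(self):
        counts = genus_summary([("s__Bacteroides_fragilis", "s__Alistipes_putredinis"),
                                ("s__Alistipes_putredinis", "s__Bacteroides_dorei")])
        assert counts == Counter({("Alistipes", "Bacteroides"): 2})

    def test_total_conserved_and_unparsable(self):
        edges = [("s__A_x", "s__B_y"), ("", "s__B_y")]
        counts = genus_summary(edges)
        assert sum(counts.values()) == len(edges)
        assert genus_of("") == "unknown"


def test_edges_to_frame_columns():
    e = EdgeMeta(("a", "b"), {"g1": 0.2, "g2": 0.9}, {"g1": 12, "g2": 12})
    heterogeneity_fdr([e])
    frame = edges_to_frame([e])
    assert {"feature_a", "feature_b", "r_g1", "r_g2", "Q", "p", "fdr"} <= set(frame.columns)
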