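import itertools

import numpy as np
import pandas as pd
import pytest

from coabnet.data_model import FeatureTable, SampleMeta
from coabnet.delta_assoc import (
    DeltaAssociation,
    call_group_specific,
    compute_deltas,
    screen_all_groups,
    spearman_screen,
    spearman_with_p,
)


def _meta_and_table(values_by_calf_day, group="CON"):
    """values_by_calf_day: {(calf, day): row-vector}."""
    meta, cols = [], {}
    for (calf, day), vals in values_by_calf_day.items():
        sid = f"{calf}_d{day}"
        meta.append(SampleMeta(sid, calf, group, day, 1000))
        cols[sid] = np.asarray(vals, dtype=float)
    n_feat = len(next(iter(values_by_calf_day.values())))
    df = pd.DataFrame(cols, index=[f"f{i}" for i in range(n_feat)])
    return FeatureTable(df, scale="raw"), meta


class TestComputeDeltas:
    def test_simple_subtraction(self):
        table, meta = _meta_and_table({("c1", 15): [2.0], ("c1", 35): [5.0]})
        delta = compute_deltas(table, meta, 15, 35)
        assert delta.data.loc["f0", "c1"] == 3.0
        assert delta.interval == (15, 35)

    def test_calf_missing_a_day_is_excluded(self):
        table, meta = _meta_and_table(
            {("c1", 15): [1.0], ("c1", 35): [2.0], ("c2", 15): [1.0]}
        )
        delta = compute_deltas(table, meta, 15, 35)
        assert delta.calves == ["c1"]

    def test_equal_days_rejected(self):
        table, meta = _meta_and_table({("c1", 15): [1.0]})
        with pytest.raises(ValueError):
            compute_deltas(table, meta, 15, 15)


class TestSpearmanScreen:
    def test_perfect_monotone(self):
        r, _ = spearman_with_p(np.arange(6.0), np.exp(np.arange(6.0)))
        assert r == pytest.approx(1.0)
        r, _ = spearman_with_p(np.arange(6.0), -np.arange(6.0))
        assert r == pytest.approx(-1.0)

    def test_exact_small_sample_p(self):
        """n=5, one adjacent swap: rho = 0.9; exhaustive enumeration over
        the 120 rank permutations gives two-sided p = 10/120."""
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.0, 2, 3, 5, 4])
        r, p = spearman_with_p(x, y)
        assert r == pytest.approx(0.9)
        # independent brute force
        base = np.arange(1.0, 6)
        hits = sum(
            abs(1 - 6 * np.sum((base - np.array(perm)) ** 2) / (5 * 24)) >= 0.9 - 1e-12
            for perm in itertools.permutations(range(1, 6))
        )
        assert p == pytest.approx(hits / 120)
        assert p == pytest.approx(1 / 12)
        assert not (abs(r) > 0.7 and p < 0.01)  # fails the dual threshold

    def test_null_false_positive_rate(self):
        """Independent deltas: ~1% of pairs reach p < 0.01 at n = 10."""
        rng = np.random.default_rng(0)
        hits = tot = 0
        for _ in range(10):
            for _ in range(100):
                r, p = spearman_with_p(rng.normal(size=10), rng.normal(size=10))
                tot += 1
                hits += p < 0.01
        tol = 2.6 * np.sqrt(0.01 * 0.99 / tot)
        assert hits / tot < 0.01 + tol

    def test_planted_relationship_recovered(self):
        """True Spearman rho 0.9 at n = 10 passes the dual threshold in > 70%."""
        rng = np.random.default_rng(1)
        rho_pearson = 2 * np.sin(np.pi * 0.9 / 6)  # Pearson giving Spearman 0.9
        cov = [[1, rho_pearson], [rho_pearson, 1]]
        flagged = 0
        reps = 100
        for _ in range(reps):
            z = rng.multivariate_normal([0, 0], cov, size=10)
            r, p = spearman_with_p(z[:, 0], z[:, 1])
            flagged += abs(r) > 0.7 and p < 0.01
        assert flagged / reps > 0.7

    def test_screen_flags_and_skips_constant(self):
        table, meta = _meta_and_table(
            {("c%d" % k, d): [k * 1.0, 7.0] for k in range(6) for d in (15, 35)}
        )
        micro = compute_deltas(table, meta, 15, 35)
        # micro deltas: f0 all zero (constant), f1 constant -> screen vs itself
        trait = compute_deltas(table, meta, 15, 35)
        out = spearman_screen(micro, trait)
        assert out == []  # all-constant deltas are skipped, not errors

    def test_scope_requires_five_calves(self):
        table, meta = _meta_and_table({("c1", 15): [1.0], ("c1", 35): [2.0]})
        delta = compute_deltas(table, meta, 15, 35)
        with pytest.raises(ValueError, match=">= 5"):
            spearman_screen(delta, delta)


def _assoc(r, p, group, sig=None):
    if sig is None:
        sig = abs(r) > 0.7 and p < 0.01
    return DeltaAssociation("m", "t", (15, 35), group, r, p, 10, sig)


class TestGroupSpecificity:
    def test_definition_case(self):
        per = {"RMT": _assoc(0.85, 0.004, "RMT"), "CON": _assoc(0.1, 0.6, "CON"),
               "RFT": _assoc(0.2, 0.4, "RFT")}
        assert call_group_specific(per, focal="RMT")

    def test_two_significant_same_sign_is_not_specific(self):
        per = {"RMT": _assoc(0.85, 0.004, "RMT"), "CON": _assoc(0.8, 0.005, "CON"),
               "RFT": _assoc(0.0, 0.9, "RFT")}
        assert not call_group_specific(per, focal="RMT")

    def test_opposite_direction_still_specific(self):
        per = {"RMT": _assoc(0.8, 0.004, "RMT"), "CON": _assoc(-0.75, 0.008, "CON"),
               "RFT": _assoc(0.1, 0.8, "RFT")}
        assert call_group_specific(per, focal="RMT")

    def test_missing_group_treated_as_not_significant(self):
        per = {"RMT": _assoc(0.85, 0.004, "RMT"), "CON": None, "RFT": _assoc(0.1, 0.9, "RFT")}
        assert call_group_specific(per, focal="RMT")

    def test_invariant_to_nonfocal_ordering(self):
        per = {"RMT": _assoc(0.85, 0.004, "RMT"), "CON": _assoc(0.1, 0.6, "CON"),
               "RFT": _assoc(-0.9, 0.003, "RFT")}
        flipped = {k: per[k] for k in ["RFT", "CON", "RMT"]}
        assert call_group_specific(per) == call_group_specific(flipped)


def test_screen_all_groups_frame():
    rng = np.random.default_rng(2)
    values = {}
    meta = []
    cols = {}
    for group in ("CON", "RMT", "RFT"):
        for k in range(6):
            calf = f"{group}{k}"
            for day in (15, 35):
                sid = f"{calf}_d{day}"
                meta.append(SampleMeta(sid, calf, group, day, 1000))
                cols[sid] = rng.normal(size=3)
    table = FeatureTable(pd.DataFrame(cols, index=["f0", "f1", "f2"]).abs(), scale="raw")
    micro = compute_deltas(table, meta, 15, 35)
    trait = compute_deltas(table, meta, 15, 35)
    frame = screen_all_groups(micro, trait)
    assert {"microbial_feature", "trait", "r_RMT", "p_RMT", "RMT_specific"} <= set(frame.columns)
    # self-pairs are perfectly correlated in every group -> never specific
    self_rows = frame[frame.microbial_feature == frame.trait]
    assert not self_rows["RMT_specific"].any()
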