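"""Differential testing of features across time points and groups.

Microbial tables are CLR + inverse-rank transformed upstream; phenotype
tables are tested untransformed.  The workhorse is the tie-corrected
Kruskal-Wallis test per feature (time points within a group, or groups
within a time point) with BH control, Dunn's z for pairwise post hoc
contrasts, plus Fisher's exact test for diarrhea incidence counts and
the Wilcoxon rank-sum test for two-group continuous contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import FeatureTable, SampleMeta, meta_by_sample
from .transforms import TransformedTable, clr_inverse_rank


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p: float


@dataclass
class DiffResult:
    feature: str
    axis: str  # time_within_group | group_within_time | overall
    statistic: float
    p: float
    fdr: float | None = None
    posthoc: list[PairwiseResult] = field(default_factory=list)


# ---------------------------------------------------------------------------


def kruskal_test(values: Sequence[float], strata: Sequence) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p on (k - 1) df.

    All-identical values give H = 0, p = 1 rather than an error.
    """
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    groups = [values[strata == s] for s in pd.unique(strata)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_test needs >= 2 non-empty strata")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(values: Sequence[float], strata: Sequence) -> list[PairwiseResult]:
    """Dunn's pairwise z tests on mean ranks with tie-corrected variance.

    z_ab = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - T)(1/n_a + 1/n_b)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups.  p values are
    two-sided and unadjusted; the family-level decision is made on the
    Kruskal FDR.
    """
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    labels = list(pd.unique(strata))
    n_total = len(values)
    ranks = stats.rankdata(values, method="average")
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    for a, b in itertools.combinations(labels, 2):
        ra, rb = ranks[strata == a], ranks[strata == b]
        if len(ra) == 0 or len(rb) == 0:
            continue
        var = base_var * (1.0 / len(ra) + 1.0 / len(rb))
        if var <= 0:
            z = 0.0
        else:
            z = (ra.mean() - rb.mean()) / np.sqrt(var)
        p = 2 * stats.norm.sf(abs(z))
        out.append(PairwiseResult(pair=(str(a), str(b)), z=float(z), p=float(min(p, 1.0))))
    return out


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns the sample odds ratio (with 0.5 continuity only when a
    margin cell is zero, for display) and the conditional hypergeometric
    p value.  A zero row or column margin gives p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact needs a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    if (t == 0).any():
        tc = t + 0.5
        odds = (tc[0, 0] * tc[1, 1]) / (tc[0, 1] * tc[1, 0])
    else:
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p)


def fisher_rxc(table: Sequence[Sequence[int]], seed: int = 0) -> float:
    """Fisher-style test for an r x c count table.

    Exact network algorithm is out of reach without specialised code, so
    a Monte Carlo chi-square permutation p is used for small tables and
    the chi-square approximation otherwise.
    """
    t = np.asarray(table, dtype=int)
    if t.sum() <= 200:
        res = stats.chi2_contingency(t)
        # Monte Carlo on the contingency table via permutation of labels
        rng = np.random.default_rng(seed)
        rows = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
        cols = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))
        obs = res.statistic
        n_mc, exceed = 2000, 0
        for _ in range(n_mc):
            perm = rng.permutation(cols)
            sim = np.zeros_like(t)
            np.add.at(sim, (rows, perm), 1)
            stat = stats.chi2_contingency(sim, correction=False).statistic if sim.min() >= 0 else 0.0
            if stat >= obs - 1e-12:
                exceed += 1
        return (1 + exceed) / (1 + n_mc)
    return float(stats.chi2_contingency(t).pvalue)


def wilcoxon_ranksum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test for two independent samples.

    Exact p for small tie-free samples, tie-corrected normal
    approximation otherwise.  Returns (U, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_ranksum needs two non-empty samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# feature-table driver


def differential_features(
    table: FeatureTable | TransformedTable,
    meta: Sequence[SampleMeta],
    axis: str = "time",
    transform: str = "none",
    fdr_level: float = 0.05,
) -> list[DiffResult]:
    """Kruskal + Dunn per feature, stratified per the requested axis.

    ``axis='time'`` tests day differences within each group;
    ``axis='group'`` tests group differences within each day.
    ``transform='clr_irn'`` applies CLR + inverse-rank first (microbial
    tables); phenotypes are tested raw.  BH adjustment is applied per
    (axis stratum) family across features.
    """
    if transform == "clr_irn":
        if isinstance(table, TransformedTable):
            raise ValueError("table already transformed")
        table = clr_inverse_rank(table)
    lookup = meta_by_sample(meta)
    samples = [s for s in table.data.columns if s in lookup]
    if axis == "time":
        strata_outer = sorted({lookup[s].group for s in samples})
        outer_of = lambda s: lookup[s].group
        inner_of = lambda s: lookup[s].day
        tag = "time_within_group"
    elif axis == "group":
        strata_outer = sorted({lookup[s].day for s in samples})
        outer_of = lambda s: lookup[s].day
        inner_of = lambda s: lookup[s].group
        tag = "group_within_time"
    else:
        raise ValueError("axis must be 'time' or 'group'")
    results: list[DiffResult] = []
    for outer in strata_outer:
        cols = [s for s in samples if outer_of(s) == outer]
        labels = [inner_of(s) for s in cols]
        if len(set(labels)) < 2:
            continue
        block: list[DiffResult] = []
        for feat in table.data.index:
            vals = table.data.loc[feat, cols].to_numpy(dtype=float)
            h, p = kruskal_test(vals, labels)
            res = DiffResult(feature=f"{feat}@{outer}", axis=tag, statistic=h, p=p)
            if len(set(labels)) >= 3:
                res.posthoc = dunn_posthoc(vals, labels)
            block.append(res)
        adj = bh_fdr([r.p for r in block])
        for r, a in zip(block, adj):
            r.fdr = float(a)
        results.extend(block)
    return results


def diff_to_frame(results: list[DiffResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"feature": r.feature, "axis": r.axis, "H": r.statistic, "p": r.p, "fdr": r.fdr}
        for ph in r.posthoc:
            key = f"dunn_{ph.pair[0]}_vs_{ph.pair[1]}"
            row[f"{key}_z"] = ph.z
            row[f"{key}_p"] = ph.p
        rows.append(row)
    return pd.DataFrame(rows)
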