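"""Differential coabundance analysis across subgroups.

Each (group, day) subgroup is treated as one study: per edge, SparCC
correlations are Fisher-z transformed and tested for heterogeneity with
Cochran's Q under inverse-variance weighting, with BH control at FDR
0.05.  Heterogeneous edges are then assigned to a single group when
exactly one effect size falls outside the Q1 - 0.75 IQR / Q3 + 0.75 IQR
fences, and hub nodes of each group-specific subnetwork are scored by
the principal eigenvector of the weighted adjacency matrix (Kleinberg
hub score, max-normalized per connected component).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Subgroup
from .diff_features import bh_fdr
from .sparcc import SubgroupNetwork

logger = logging.getLogger(__name__)

#: clip r away from +-1 before atanh
_R_CLIP = 0.999


@dataclass
class EdgeMeta:
    """One edge of the union network with per-subgroup effects and Q test."""

    edge: tuple[str, str]
    effect_sizes: dict[str, float]  # subgroup label -> r
    ns: dict[str, int]  # subgroup label -> sample count
    Q: float | None = None
    p: float | None = None
    fdr: float | None = None
    heterogeneous: bool = False


@dataclass
class SpecificityCall:
    edge: tuple[str, str]
    quartiles: tuple[float, float]
    iqr: float
    outlier_group: str | None
    direction: str  # low | high | none


@dataclass
class HubScore:
    node: str
    score: float

    @property
    def is_hub(self) -> bool:
        return self.score > 0.5


# ---------------------------------------------------------------------------


def edge_universe(
    networks: list[SubgroupNetwork],
    r_matrices: dict[str, pd.DataFrame],
) -> list[EdgeMeta]:
    """Union of edges significant in at least one subgroup.

    Effect sizes are filled from every subgroup's full r matrix,
    regardless of where the edge reached significance; an edge touching
    a feature absent from some subgroup's matrix has a missing effect
    there (logged).
    """
    union: set[tuple[str, str]] = set()
    ns: dict[str, int] = {}
    for net in networks:
        ns[net.subgroup.label] = net.n_samples
        union |= net.edge_set()
    out = []
    for a, b in sorted(union):
        effects: dict[str, float] = {}
        for label, r in r_matrices.items():
            if a in r.index and b in r.columns:
                val = float(r.loc[a, b])
                effects[label] = val if np.isfinite(val) else np.nan
            else:
                logger.warning("edge (%s, %s): features absent from subgroup %s", a, b, label)
                effects[label] = np.nan
        out.append(EdgeMeta(edge=(a, b), effect_sizes=effects, ns={k: ns.get(k, 0) for k in r_matrices}))
    return out


def fisher_z(r: float) -> float:
    return float(np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP)))


def cochran_q(effect_sizes: dict[str, float], ns: dict[str, int]) -> tuple[float, float] | None:
    """Cochran's Q heterogeneity test on Fisher-z correlations.

    z_k = atanh(r_k) with variance 1/(n_k - 3); Q = sum w_k (z_k - zbar)^2
    with w_k = 1/v_k and zbar the inverse-variance pooled effect; the p
    value is the upper chi-square tail with (k - 1) degrees of freedom.
    Subgroups with n <= 3 are dropped (their z variance is undefined);
    fewer than 2 usable subgroups yields None.
    """
    z, w = [], []
    for label, r in effect_sizes.items():
        n = ns.get(label, 0)
        if r is None or not np.isfinite(r):
            continue
        if n <= 3:
            logger.warning("subgroup %s dropped from Q test: n = %d <= 3", label, n)
            continue
        z.append(fisher_z(r))
        w.append(n - 3.0)
    if len(z) < 2:
        return None
    z_arr = np.asarray(z)
    w_arr = np.asarray(w)
    pooled = float(np.sum(w_arr * z_arr) / np.sum(w_arr))
    q = float(np.sum(w_arr * (z_arr - pooled) ** 2))
    p = float(stats.chi2.sf(q, df=len(z) - 1))
    return q, max(p, np.finfo(float).tiny)


def heterogeneity_fdr(edges: list[EdgeMeta], fdr_level: float = 0.05) -> list[EdgeMeta]:
    """Fill Q, p and BH-adjusted fdr on every edge; flag fdr < level.

    Edges whose Q test is not computable keep missing values and do not
    enter the BH family.
    """
    for e in edges:
        res = cochran_q(e.effect_sizes, e.ns)
        if res is not None:
            e.Q, e.p = res
    tested = [e for e in edges if e.p is not None]
    if tested:
        adjusted = bh_fdr(np.array([e.p for e in tested]))
        for e, a in zip(tested, adjusted):
            e.fdr = float(a)
            e.heterogeneous = e.fdr < fdr_level
    return edges


def iqr_specificity(
    effect_sizes: dict[str, float],
    factor: float = 0.75,
    edge: tuple[str, str] = ("", ""),
) -> SpecificityCall:
    """Assign an edge to one subgroup by the IQR outlier fence rule.

    Quartiles use linear interpolation between order statistics (the
    convention matters at k = 3).  A candidate is the minimum if it lies
    strictly below Q1 - factor*IQR, or the maximum if strictly above
    Q3 + factor*IQR; the edge is called specific only when exactly one
    candidate exists and the extreme value is unique.
    """
    labels = list(effect_sizes)
    values = np.array([effect_sizes[g] for g in labels], dtype=float)
    if np.isnan(values).any():
        logger.warning("edge %s: missing effect size, no specificity call", edge)
        return SpecificityCall(edge, (np.nan, np.nan), np.nan, None, "none")
    q1, q3 = np.percentile(values, [25, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    low_fence = q1 - factor * iqr
    high_fence = q3 + factor * iqr
    candidates: list[tuple[str, str]] = []
    vmin, vmax = values.min(), values.max()
    if vmin < low_fence and np.sum(values == vmin) == 1:
        candidates.append((labels[int(np.argmin(values))], "low"))
    if vmax > high_fence and np.sum(values == vmax) == 1:
        candidates.append((labels[int(np.argmax(values))], "high"))
    if len(candidates) == 1:
        group, direction = candidates[0]
        return SpecificityCall(edge, (float(q1), float(q3)), float(iqr), group, direction)
    return SpecificityCall(edge, (float(q1), float(q3)), float(iqr), None, "none")


def call_specific_edges(
    edges: list[EdgeMeta],
    subgroup_labels: list[str],
    factor: float = 0.75,
) -> list[SpecificityCall]:
    """IQR specificity over the given subgroups, for heterogeneous edges only."""
    calls = []
    for e in edges:
        if not e.heterogeneous:
            continue
        effects = {g: e.effect_sizes.get(g, np.nan) for g in subgroup_labels}
        calls.append(iqr_specificity(effects, factor=factor, edge=e.edge))
    return calls


def hub_scores(edges: list[tuple[str, str, float]]) -> list[HubScore]:
    """Kleinberg hub scores of an undirected weighted graph.

    For an undirected graph, hub and authority scores coincide with the
    principal eigenvector of the weighted adjacency matrix.  Scores are
    normalized so the maximum within each connected component is 1;
    a node is a hub when its score exceeds 0.5.  Edge weights are |r|.
    """
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=abs(w))
    out: list[HubScore] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nodes = sorted(sub.nodes)
        adj = nx.to_numpy_array(sub, nodelist=nodes, weight="weight")
        eigvals, eigvecs = np.linalg.eigh(adj)
        principal = np.abs(eigvecs[:, np.argmax(eigvals)])
        principal /= principal.max()
        out.extend(HubScore(node=n, score=float(s)) for n, s in zip(nodes, principal))
    out.sort(key=lambda h: (-h.score, h.node))
    return out


def genus_of(species: str) -> str:
    """Genus from a MetaPhlAn-style species id (``s__Genus_species``)."""
    name = species.split("|")[-1]
    if name.startswith("s__"):
        name = name[3:]
    parts = name.split("_")
    if not parts or not parts[0]:
        logger.warning("unparsable species name %r; genus set to 'unknown'", species)
        return "unknown"
    return parts[0]


def genus_summary(edges: list[tuple[str, str]]) -> Counter:
    """Count flagged edges by unordered genus pair (same-genus pairs included)."""
    counts: Counter = Counter()
    for a, b in edges:
        pair = tuple(sorted((genus_of(a), genus_of(b))))
        counts[pair] += 1
    return counts


# ---------------------------------------------------------------------------
# tabular output


def edges_to_frame(edges: list[EdgeMeta], calls: list[SpecificityCall] | None = None) -> pd.DataFrame:
    call_by_edge = {c.edge: c for c in calls} if calls else {}
    labels = sorted({g for e in edges for g in e.effect_sizes})
    rows = []
    for e in edges:
        row: dict = {"feature_a": e.edge[0], "feature_b": e.edge[1]}
        for g in labels:
            row[f"r_{g}"] = e.effect_sizes.get(g, np.nan)
        row.update(Q=e.Q, p=e.p, fdr=e.fdr, heterogeneous=e.heterogeneous)
        call = call_by_edge.get(e.edge)
        row["specific_group"] = call.outlier_group if call and call.outlier_group else ""
        rows.append(row)
    return pd.DataFrame(rows)
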