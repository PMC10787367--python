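"""SparCC: basis correlations from compositional count data.

Relative abundances carry a unit-sum constraint that induces spurious
negative correlations; SparCC instead estimates correlations between the
latent *basis* abundances.  It works from the log-ratio variance matrix

    t_ij = var(log(x_i / x_j))

which, writing omega_i for the basis log-variance of feature i and
rho_ij for the basis correlation, satisfies

    t_ij = omega_i + omega_j - 2 rho_ij sqrt(omega_i omega_j).

Under the sparsity assumption (most rho_ij ~ 0) the omega are obtained
from the linear system sum_j t_ij ~ (D - 2) omega_i + sum_k omega_k, and
rho follows by inversion.  Strongly correlated pairs violate sparsity,
so the most correlated pair is excluded from the system and the solve is
repeated for a fixed number of rounds.  Sampling noise in the observed
fractions is handled by averaging over Dirichlet-resampled fractions
(counts + 1 posterior); significance comes from permuting each feature's
counts across samples independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .data_model import FeatureTable, Subgroup

logger = logging.getLogger(__name__)


@dataclass
class SparccConfig:
    """Tuning parameters for basis-correlation inference.

    Defaults follow the reference algorithm: 20 Dirichlet resamples
    aggregated by the median, 10 exclusion rounds at |r| > 0.1, and a
    two-sided permutation test with 100 permutations at alpha = 0.01.
    """

    n_inner_iterations: int = 20
    n_exclusion_rounds: int = 10
    exclusion_threshold: float = 0.1
    n_permutations: int = 100
    alpha: float = 0.01
    seed: int = 0
    aggregate: Literal["median", "mean"] = "median"
    point_estimate: bool = False  # deterministic mode: fractions = (counts + 1) / sum

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.exclusion_threshold < 1:
            raise ValueError("exclusion_threshold must be in (0, 1)")


@dataclass
class Edge:
    feature_a: str
    feature_b: str
    r: float
    p: float


@dataclass
class SubgroupNetwork:
    """Significant coabundance edges for one (group, day) subgroup."""

    subgroup: Subgroup
    edges: list[Edge]
    n_samples: int

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.feature_a, e.feature_b) for e in self.edges}


# ---------------------------------------------------------------------------
# core algorithm


def _variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i / x_j)) over samples; fractions is features x samples."""
    logf = np.log(fractions)
    n = logf.shape[1]
    # var(log xi - log xj) = var_i + var_j - 2 cov_ij (population variance, ddof=1)
    cov = np.cov(logf, ddof=1)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2 * cov


def _basis_correlations_from_t(
    t: np.ndarray,
    n_exclusion_rounds: int,
    exclusion_threshold: float,
) -> np.ndarray:
    """Solve basis variances under sparsity with iterative pair exclusion.

    Returns the correlation matrix; rows/columns whose basis variance
    went nonpositive are NaN (flagged by the caller).
    """
    d = t.shape[0]
    if d < 4:
        raise ValueError("SparCC needs at least 4 features")
    # M omega = t_row_sums with M = (d - 2) I + 1 1^T before exclusions
    mask = np.ones_like(t, dtype=bool)  # pair (i, j) participates
    np.fill_diagonal(mask, False)
    excluded: set[tuple[int, int]] = set()

    def solve() -> tuple[np.ndarray, np.ndarray]:
        m = np.ones((d, d))
        np.fill_diagonal(m, d - 1)
        for i, j in excluded:
            m[i, i] -= 1
            m[j, j] -= 1
            m[i, j] -= 1
            m[j, i] -= 1
        tsum = np.where(mask, t, 0.0).sum(axis=1)
        omega = np.linalg.solve(m, tsum)
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = 2 * np.sqrt(np.outer(omega, omega))
            r = (omega[:, None] + omega[None, :] - t) / denom
        bad = omega <= 0
        if bad.any():
            r[bad, :] = np.nan
            r[:, bad] = np.nan
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        return omega, r

    omega, r = solve()
    for _ in range(n_exclusion_rounds):
        cand = np.abs(r).copy()
        np.fill_diagonal(cand, 0.0)
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
        cand[np.isnan(cand)] = 0.0
        if cand.max() <= exclusion_threshold:
            break
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        i, j = int(min(i, j)), int(max(i, j))
        # stop if excluding would leave a feature with fewer than 3 partners
        partners = mask.sum(axis=1)
        if partners[i] <= 3 or partners[j] <= 3:
            break
        excluded.add((i, j))
        mask[i, j] = mask[j, i] = False
        omega, r = solve()
    return r


def _resampled_fractions(counts: np.ndarray, rng: np.random.Generator, point_estimate: bool) -> np.ndarray:
    """One draw of fractions per sample from the Dirichlet(counts + 1) posterior."""
    if point_estimate:
        pseudo = counts + 1.0
        return pseudo / pseudo.sum(axis=0, keepdims=True)
    d, n = counts.shape
    out = np.empty((d, n))
    for j in range(n):
        out[:, j] = rng.dirichlet(counts[:, j] + 1.0)
    return out


def _sparcc_r_from_counts(counts: np.ndarray, config: SparccConfig, rng: np.random.Generator) -> np.ndarray:
    iters = 1 if config.point_estimate else config.n_inner_iterations
    draws = np.empty((iters, counts.shape[0], counts.shape[0]))
    for k in range(iters):
        fractions = _resampled_fractions(counts, rng, config.point_estimate)
        t = _variation_matrix(fractions)
        draws[k] = _basis_correlations_from_t(t, config.n_exclusion_rounds, config.exclusion_threshold)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # all-NaN cells are expected when a feature's basis variance degenerates
        _warnings.filterwarnings("ignore", message="All-NaN slice", category=RuntimeWarning)
        _warnings.filterwarnings("ignore", message="Mean of empty slice", category=RuntimeWarning)
        if config.aggregate == "median":
            r = np.nanmedian(draws, axis=0)
        else:
            r = np.nanmean(draws, axis=0)
    # a feature NaN in every draw stays NaN
    all_nan = np.isnan(draws).all(axis=0)
    r[all_nan] = np.nan
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def sparcc_correlations(counts: FeatureTable, config: SparccConfig | None = None) -> pd.DataFrame:
    """Estimate the basis correlation matrix from a count-scale table.

    Requires at least 4 features and 4 samples.  Features whose basis
    variance turns nonpositive after exclusion are flagged with warnings
    and their correlations set to NaN.
    """
    config = config or SparccConfig()
    if counts.scale not in ("count", "intensity"):
        raise ValueError(f"sparcc_correlations expects counts, got scale {counts.scale!r}")
    if counts.n_features < 4:
        raise ValueError("SparCC needs at least 4 features")
    if counts.n_samples < 4:
        raise ValueError("SparCC needs at least 4 samples")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    r = _sparcc_r_from_counts(counts.values, config, rng)
    nan_rows = np.flatnonzero(np.isnan(r).all(axis=1) | np.isnan(np.diag(r)))
    for i in nan_rows:
        logger.warning("feature %r: nonpositive basis variance; correlations set to missing",
                       counts.feature_ids[i])
    return pd.DataFrame(r, index=counts.feature_ids, columns=counts.feature_ids)


def permutation_pvalues(
    counts: FeatureTable,
    observed_r: pd.DataFrame,
    config: SparccConfig | None = None,
) -> pd.DataFrame:
    """Two-sided permutation p-values for each SparCC correlation.

    Each permutation shuffles every feature's counts across samples
    independently (destroying all between-feature dependence while
    preserving marginals) and reruns the estimator.  With the +1
    pseudocount, p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), so the
    minimum attainable p with 100 permutations is 1/101 < 0.01.
    """
    config = config or SparccConfig()
    obs = np.abs(observed_r.to_numpy(dtype=float))
    exceed = np.zeros_like(obs)
    ss = np.random.SeedSequence(config.seed).spawn(2 + config.n_permutations)
    x = counts.values
    for k in range(config.n_permutations):
        rng = np.random.default_rng(ss[2 + k])
        permuted = np.empty_like(x)
        for i in range(x.shape[0]):
            permuted[i] = rng.permutation(x[i])
        r_perm = _sparcc_r_from_counts(permuted, config, rng)
        with np.errstate(invalid="ignore"):
            exceed += (np.abs(r_perm) >= obs).astype(float)
    p = (1.0 + exceed) / (1.0 + config.n_permutations)
    p[np.isnan(obs)] = np.nan
    np.fill_diagonal(p, np.nan)
    return pd.DataFrame(p, index=observed_r.index, columns=observed_r.columns)


def significant_edges(
    r: pd.DataFrame,
    p: pd.DataFrame,
    subgroup: Subgroup,
    n_samples: int,
    alpha: float = 0.01,
) -> SubgroupNetwork:
    """Extract the p < alpha edges as a canonically ordered edge list."""
    features = list(r.index)
    rv = r.to_numpy(dtype=float)
    pv = p.to_numpy(dtype=float)
    edges = []
    for i in range(len(features)):
        for j in range(i + 1, len(features)):
            if np.isnan(pv[i, j]):
                continue
            if pv[i, j] < alpha:
                a, b = sorted((features[i], features[j]))
                edges.append(Edge(a, b, float(rv[i, j]), float(pv[i, j])))
    edges.sort(key=lambda e: (e.feature_a, e.feature_b))
    return SubgroupNetwork(subgroup=subgroup, edges=edges, n_samples=n_samples)


def infer_network(
    counts: FeatureTable,
    subgroup: Subgroup,
    config: SparccConfig | None = None,
) -> tuple[SubgroupNetwork, pd.DataFrame, pd.DataFrame]:
    """Run the full SparCC inference for one subgroup: r, permutation p, edges."""
    config = config or SparccConfig()
    r = sparcc_correlations(counts, config)
    p = permutation_pvalues(counts, r, config)
    net = significant_edges(r, p, subgroup, counts.n_samples, alpha=config.alpha)
    return net, r, p


def write_edge_list(net: SubgroupNetwork, path) -> None:
    pd.DataFrame(
        [(e.feature_a, e.feature_b, e.r, e.p) for e in net.edges],
        columns=["feature_a", "feature_b", "r", "p"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_edge_list(path, subgroup: Subgroup, n_samples: int) -> SubgroupNetwork:
    df = pd.read_csv(path, sep="\t", dtype={"feature_a": str, "feature_b": str})
    edges = [Edge(row.feature_a, row.feature_b, float(row.r), float(row.p)) for row in df.itertuples()]
    return SubgroupNetwork(subgroup=subgroup, edges=edges, n_samples=n_samples)
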