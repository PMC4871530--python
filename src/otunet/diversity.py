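"""Alpha diversity, Bray-Curtis beta diversity, NMDS and permutation tests.

Alpha diversity is the Shannon index (nats by default) and rarefaction-based
expected richness. Beta diversity is Bray-Curtis, ordinated by non-metric
multidimensional scaling, and group structure is tested three ways —
ANOSIM, one-factor PERMANOVA, and an envfit-style factor fit to the
ordination — all with seeded label-permutation nulls. Within-group
dispersion (all within-group pairwise dissimilarities) is compared across
groups with the same Kruskal-Wallis / Holm-Mann-Whitney battery used for
abundance data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from sklearn.manifold import smacof

from .differential import GroupComparison, compare_group_values
from .tables_io import OtuTable

__all__ = [
    "shannon",
    "rarefied_richness",
    "bray_curtis",
    "nmds",
    "OrdinationResult",
    "PermutationTestResult",
    "anosim",
    "permanova",
    "envfit_factor",
    "intragroup_dispersion",
    "DispersionResult",
]


# --------------------------------------------------------------------------
# alpha diversity
# --------------------------------------------------------------------------

def shannon(counts: Sequence[float], base: float | None = None) -> float:
    """Shannon entropy -sum(p ln p) of one sample's taxon proportions.

    Natural log by default (the convention of the standard ecology
    toolkits); pass ``base`` to change it.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon entropy is undefined for an all-zero sample")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def rarefied_richness(counts: Sequence[float], depth: int = 5000) -> float:
    """Expected number of taxa observed in a uniform subsample of ``depth``.

    E(S) = sum_i [1 - C(N - N_i, depth) / C(N, depth)], evaluated in
    log-space with gammaln so large binomial coefficients stay finite.
    """
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    total = x.sum()
    if depth <= 0:
        raise ValueError("depth must be positive")
    if total < depth:
        raise ValueError(f"sample total {total:.0f} is below depth {depth}")

    # log C(N - Ni, depth) - log C(N, depth); hypergeometric miss probability
    n = total
    with np.errstate(invalid="ignore"):
        log_miss = (
            gammaln(n - x + 1)
            - gammaln(depth + 1)
            - gammaln(n - x - depth + 1)
            - (gammaln(n + 1) - gammaln(depth + 1) - gammaln(n - depth + 1))
        )
    miss = np.where(n - x < depth, 0.0, np.exp(log_miss))
    return float(np.sum(1.0 - miss))


# --------------------------------------------------------------------------
# beta diversity and ordination
# --------------------------------------------------------------------------

def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix d(i,j) = sum|x-y| / sum(x+y)."""
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    if (table.sample_totals() == 0).any():
        raise ValueError("Bray-Curtis is undefined for all-zero samples")
    return beta_diversity(
        "braycurtis", table.counts.to_numpy(), ids=table.sample_ids
    )


@dataclass
class OrdinationResult:
    """NMDS configuration, its Kruskal stress-1 and restart bookkeeping."""

    coordinates: pd.DataFrame  # samples x k
    stress: float
    restart_stresses: list[float]
    seed: int | None
    converged: bool = True

    @property
    def n_restarts(self) -> int:
        return len(self.restart_stresses)


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson classical scaling used to initialize NMDS."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 500,
    eps: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Each restart runs SMACOF with isotonic (monotone) regression of the
    dissimilarities against configuration distances, initialized from
    classical scaling plus Gaussian jitter (the first restart is unjittered).
    The best-stress configuration wins.
    """
    dm = d.data
    n = dm.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for a {k}-D ordination")
    rng = np.random.default_rng(seed)
    base_init = _classical_scaling(dm, k)
    scale = max(base_init.std(), 1e-8)

    best_coords, best_stress = None, np.inf
    restart_stresses: list[float] = []
    for r in range(n_restarts):
        init = base_init if r == 0 else base_init + rng.normal(0, 0.05 * scale, base_init.shape)
        coords, stress = smacof(
            dm,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=eps,
            normalized_stress=True,
        )
        restart_stresses.append(float(stress))
        if stress < best_stress:
            best_coords, best_stress = coords, float(stress)

    coords = pd.DataFrame(
        best_coords, index=list(d.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=coords,
        stress=best_stress,
        restart_stresses=restart_stresses,
        seed=seed,
    )


# --------------------------------------------------------------------------
# permutation tests
# --------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    method: str
    statistic: float  # R (ANOSIM), pseudo-F (PERMANOVA), r^2 (envfit)
    p_value: float
    n_permutations: int
    seed: int | None
    extras: dict = field(default_factory=dict)  # e.g. PERMANOVA R^2


def _check_groups(ids: Sequence[str], groups: pd.Series | dict) -> np.ndarray:
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    labels = groups.loc[list(ids)].to_numpy()
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")
    return codes


def _permuted_codes(codes: np.ndarray, nperm: int, rng: np.random.Generator) -> np.ndarray:
    n = codes.size
    perms = np.empty((nperm, n), dtype=codes.dtype)
    for b in range(nperm):
        perms[b] = codes[rng.permutation(n)]
    return perms


def _perm_pvalue(obs: float, null: np.ndarray, nperm: int) -> float:
    # (1+b)/(1+nperm): the identity permutation counts as one tie
    exceed = int(np.sum(null >= obs - 1e-12))
    return (1 + exceed) / (1 + nperm)


def anosim(
    d: DistanceMatrix,
    groups: pd.Series | dict,
    nperm: int = 5000,
    seed: int | None = None,
) -> PermutationTestResult:
    """ANOSIM: R = (mean between-rank - mean within-rank) / (M/2).

    Dissimilarities are rank-transformed once (average ranks for ties);
    the permutation null shuffles group labels over samples.
    """
    codes = _check_groups(d.ids, groups)
    n = len(codes)
    dm = d.data
    iu = np.triu_indices(n, k=1)
    ranks_flat = stats.rankdata(dm[iu])
    rank_sq = np.zeros((n, n))
    rank_sq[iu] = ranks_flat
    rank_sq += rank_sq.T
    m = n * (n - 1) / 2
    denom = m / 2.0

    def r_stat(c: np.ndarray) -> float:
        within = c[:, None] == c[None, :]
        w = within[iu]
        rw = ranks_flat[w].mean()
        rb = ranks_flat[~w].mean()
        return (rb - rw) / denom

    obs = r_stat(codes)
    rng = np.random.default_rng(seed)
    null = np.empty(nperm)
    total_rank = ranks_flat.sum()
    n_within = int(np.sum(codes[:, None] == codes[None, :]) - n) // 2
    perms = _permuted_codes(codes, nperm, rng)
    # vectorized in chunks: mean within-rank per permutation via einsum
    for lo in range(0, nperm, 512):
        chunk = perms[lo : lo + 512]
        within = chunk[:, :, None] == chunk[:, None, :]
        sw = np.einsum("bij,ij->b", within, rank_sq) / 2.0
        rw = sw / n_within
        rb = (total_rank - sw) / (m - n_within)
        null[lo : lo + 512] = (rb - rw) / denom
    p = _perm_pvalue(obs, null, nperm)
    return PermutationTestResult("anosim", float(obs), p, nperm, seed)


def permanova(
    d: DistanceMatrix,
    groups: pd.Series | dict,
    nperm: int = 5000,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-factor PERMANOVA pseudo-F with a label-permutation null.

    SS_total = sum_{i<j} d_ij^2 / N; SS_within pools each group's pairwise
    squared dissimilarities divided by its size; pseudo-F =
    (SS_between/(a-1)) / (SS_within/(N-a)); R^2 = SS_between / SS_total.
    """
    codes = _check_groups(d.ids, groups)
    n = len(codes)
    a = codes.max() + 1
    d2 = d.data**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    sizes = np.bincount(codes)

    def ss_within(c: np.ndarray) -> float:
        ssw = 0.0
        for g in range(a):
            mask = c == g
            ssw += d2[np.ix_(mask, mask)].sum() / (2 * sizes[g])
        return ssw

    def pseudo_f(ssw: np.ndarray | float):
        ssb = ss_total - ssw
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ssb / (a - 1)) / (ssw / (n - a))

    obs_ssw = ss_within(codes)
    obs = pseudo_f(obs_ssw)
    r2 = (ss_total - obs_ssw) / ss_total

    rng = np.random.default_rng(seed)
    perms = _permuted_codes(codes, nperm, rng)
    null = np.empty(nperm)
    for lo in range(0, nperm, 512):
        chunk = perms[lo : lo + 512]
        ssw = np.zeros(chunk.shape[0])
        for g in range(a):
            mg = (chunk == g).astype(float)
            ssw += np.einsum("bi,ij,bj->b", mg, d2, mg) / (2 * sizes[g])
        null[lo : lo + 512] = pseudo_f(ssw)
    p = _perm_pvalue(obs, null, nperm)
    return PermutationTestResult(
        "permanova", float(obs), p, nperm, seed, extras={"R2": float(r2)}
    )


def envfit_factor(
    ordination: OrdinationResult,
    groups: pd.Series | dict,
    nperm: int = 10000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Factor fit to ordination scores: r^2 = 1 - SS_within-centroid/SS_total.

    Singleton groups are allowed (a singleton contributes zero within-
    centroid scatter); a single group overall is an error.
    """
    coords = ordination.coordinates
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    labels = groups.loc[list(coords.index)].to_numpy()
    _, codes = np.unique(labels, return_inverse=True)
    if codes.max() == 0:
        raise ValueError("need at least two groups")
    x = coords.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    ss_total = float((centered**2).sum())
    if ss_total == 0:
        raise ValueError("envfit r^2 is undefined for identical coordinates")
    a = codes.max() + 1

    def r_squared(c: np.ndarray) -> float:
        ssw = 0.0
        for g in range(a):
            pts = x[c == g]
            ssw += ((pts - pts.mean(axis=0)) ** 2).sum()
        return 1.0 - ssw / ss_total

    obs = r_squared(codes)
    rng = np.random.default_rng(seed)
    perms = _permuted_codes(codes, nperm, rng)
    sizes = np.bincount(codes).astype(float)
    sq = (x**2).sum(axis=1)
    null = np.empty(nperm)
    for lo in range(0, nperm, 1024):
        chunk = perms[lo : lo + 1024]
        ssw = np.zeros(chunk.shape[0])
        for g in range(a):
            mg = (chunk == g).astype(float)
            # SSW_g = sum |x_i|^2 - n_g |centroid|^2
            s = mg @ x  # (b, k) group sums
            ssw += mg @ sq - (s**2).sum(axis=1) / sizes[g]
        null[lo : lo + 1024] = 1.0 - ssw / ss_total
    p = _perm_pvalue(obs, null, nperm)
    return PermutationTestResult("envfit", float(obs), p, nperm, seed)


# --------------------------------------------------------------------------
# within-group dispersion
# --------------------------------------------------------------------------

@dataclass
class DispersionResult:
    """Within-group pairwise dissimilarities and their group comparison."""

    within: dict[str, np.ndarray]
    comparison: GroupComparison


def intragroup_dispersion(d: DistanceMatrix, groups: pd.Series | dict) -> DispersionResult:
    """Collect each group's within-group dissimilarities and compare them."""
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    labels = groups.loc[list(d.ids)]
    dm = d.data
    ids = np.asarray(d.ids)
    within: dict[str, np.ndarray] = {}
    for g in pd.unique(labels):
        idx = np.flatnonzero((labels == g).to_numpy())
        if idx.size < 2:
            raise ValueError(f"group {g!r} needs at least two members")
        sub = dm[np.ix_(idx, idx)]
        within[g] = sub[np.triu_indices(idx.size, k=1)]
    values = np.concatenate(list(within.values()))
    labels_flat = np.concatenate([[g] * len(v) for g, v in within.items()])
    comparison = compare_group_values(values, labels_flat)
    return DispersionResult(within=within, comparison=comparison)
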