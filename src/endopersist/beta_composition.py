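"""Bray-Curtis dissimilarity, NMDS ordination and permutation tests.

Community composition differences between seasons, sites or tissues are
assessed on a Bray-Curtis distance matrix with one-factor PERMANOVA
(pseudo-F from the squared-distance partition) and ANOSIM (rank-based R),
both with seeded label permutations, and visualised by non-metric
multidimensional scaling (Kruskal stress-1, SMACOF majorization
alternated with isotonic regression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from .data_model import AbundanceTable, TableValidationError

__all__ = [
    "DistanceMatrix",
    "PermutationTestResult",
    "NMDSResult",
    "bray_curtis",
    "permanova",
    "anosim",
    "nmds",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal not zero")

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class PermutationTestResult:
    statistic: float
    p: float
    n_perm: int
    seed: int
    method: str
    r2: float = float("nan")


@dataclass
class NMDSResult:
    coords: pd.DataFrame  # samples x k
    stress: float
    converged: bool
    stress_trajectory: np.ndarray  # of the winning start; nonincreasing


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples, on counts.

    d(j,k) = 1 - 2 * sum_i min(x_ij, x_ik) / (sum_i x_ij + sum_i x_ik).
    """
    sums = table.sample_sums().to_numpy()
    if np.any(sums <= 0):
        raise TableValidationError("zero-total sample in Bray-Curtis input")
    x = table.counts.to_numpy(dtype=float).T  # samples x taxa
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _check_groups(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(inv)
    if np.any(counts < 2):
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"groups of size 1 not allowed: {small}")
    return uniq, inv


def _permuted_labels(inv: np.ndarray, n_perm: int, rng) -> np.ndarray:
    perms = np.tile(inv, (n_perm, 1))
    return rng.permuted(perms, axis=1)


def _permanova_ss_within(d2: np.ndarray, labels2d: np.ndarray, n_groups: int):
    """SS_within for a batch of label rows: sum_g (1/n_g) sum_{i<j in g} d2."""
    ssw = np.zeros(labels2d.shape[0])
    for g in range(n_groups):
        z = (labels2d == g).astype(float)
        ng = z.sum(axis=1)
        ssw += np.einsum("pi,ij,pj->p", z, d2, z) / (2.0 * ng)
    return ssw


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """One-factor PERMANOVA pseudo-F with label-permutation p-value.

    SS_total = sum_{i<j} d_ij^2 / N; SS_within partitions by group with
    per-group size normalisation; F = (SS_b/(g-1)) / (SS_w/(N-g));
    R^2 = SS_b / SS_total; p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    labels = np.asarray(groups)
    n = len(d.labels)
    if labels.shape[0] != n:
        raise ValueError("groups length does not match distance matrix")
    uniq, inv = _check_groups(labels)
    g = uniq.size
    d2 = d.d**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def f_stat(rows: np.ndarray) -> np.ndarray:
        ssw = _permanova_ss_within(d2, rows, g)
        ssb = ss_total - ssw
        return (ssb / (g - 1)) / (ssw / (n - g))

    f_obs = float(f_stat(inv[None, :])[0])
    ssw_obs = float(_permanova_ss_within(d2, inv[None, :], g)[0])
    r2 = (ss_total - ssw_obs) / ss_total
    rng = np.random.default_rng(seed)
    f_perm = f_stat(_permuted_labels(inv, n_perm, rng))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (n_perm + 1.0)
    return PermutationTestResult(f_obs, float(p), n_perm, seed, "permanova", float(r2))


def anosim(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """ANOSIM R statistic with label-permutation p-value.

    R = (mean rank between - mean rank within) / (M/2), M = N(N-1)/2,
    ranks of all pairwise distances with average ties.
    """
    labels = np.asarray(groups)
    n = len(d.labels)
    if labels.shape[0] != n:
        raise ValueError("groups length does not match distance matrix")
    uniq, inv = _check_groups(labels)
    g = uniq.size
    cond = d.condensed()
    ranks = squareform(rankdata(cond), checks=False)
    m = n * (n - 1) / 2
    total = ranks[np.triu_indices(n, 1)].sum()

    def r_stat(rows: np.ndarray) -> np.ndarray:
        sum_w = np.zeros(rows.shape[0])
        cnt_w = np.zeros(rows.shape[0])
        for gi in range(g):
            z = (rows == gi).astype(float)
            ng = z.sum(axis=1)
            sum_w += np.einsum("pi,ij,pj->p", z, ranks, z) / 2.0
            cnt_w += ng * (ng - 1) / 2.0
        mean_w = sum_w / cnt_w
        mean_b = (total - sum_w) / (m - cnt_w)
        return (mean_b - mean_w) / (m / 2.0)

    r_obs = float(r_stat(inv[None, :])[0])
    rng = np.random.default_rng(seed)
    r_perm = r_stat(_permuted_labels(inv, n_perm, rng))
    p = (1.0 + np.sum(r_perm >= r_obs)) / (n_perm + 1.0)
    return PermutationTestResult(r_obs, float(p), n_perm, seed, "anosim")


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = np.sum(dist**2)
    if denom <= 0:
        return float("inf")
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> NMDSResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Each random start alternates isotonic regression of configuration
    distances on the input dissimilarities (yielding monotone
    disparities) with a Guttman majorization update of the
    configuration; the recorded stress trajectory is nonincreasing and
    the best configuration over ``n_starts`` starts is returned. A start
    that hits ``max_iter`` without the stress change falling below
    ``tol`` is flagged unconverged (best-so-far still returned).
    """
    n = len(d.labels)
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} samples for k={k} NMDS")
    diss = d.condensed()
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_starts)):
        x = rng.standard_normal((n, k))
        traj = []
        best_local = None
        converged = False
        prev = np.inf
        for _ in range(max_iter):
            dist = pdist(x)
            dist = np.maximum(dist, 1e-12)
            # regress distances on dissimilarities; equal dissimilarities
            # share one disparity (secondary tie treatment)
            iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
            disp = iso.fit_transform(diss, dist)
            s = _stress1(dist, disp)
            if best_local is None or s < best_local[0]:
                best_local = (s, x.copy())
            if s > prev + 1e-12:
                # stress stopped decreasing; jitter below tol still counts
                # as convergence, keep the recorded trajectory nonincreasing
                converged = s - prev < tol
                break
            traj.append(s)
            if prev - s < tol or s < 1e-4:  # stalled, or essentially perfect fit
                converged = True
                break
            prev = s
            # Guttman transform toward the disparities
            ratio = squareform(disp / dist, checks=False)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = b @ x / n
            x -= x.mean(axis=0)
        s_final, x_final = best_local
        if best is None or s_final < best[0]:
            best = (s_final, x_final, converged, np.asarray(traj))

    s_final, x_final, converged, traj = best
    if not converged:
        import warnings

        warnings.warn("NMDS did not converge in all starts; best-so-far returned")
    coords = pd.DataFrame(
        x_final, index=d.labels, columns=[f"axis{i + 1}" for i in range(k)]
    )
    return NMDSResult(coords, s_final, converged, traj)
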