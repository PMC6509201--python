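"""Alpha and beta diversity statistics for OTU community tables.

Alpha diversity: observed richness, bias-corrected Chao1
(S_obs + F1(F1-1) / (2(F2+1)), with F1/F2 the singleton/doubleton counts)
and the inverse Simpson index 1 / sum(p_i^2). Beta diversity: Bray-Curtis
dissimilarity, non-metric multidimensional scaling (NMDS) minimizing
Kruskal stress-1 with pool-adjacent-violators disparities, the ANOSIM
rank permutation test, and a Kruskal-Wallis comparison of per-group
values (e.g. thermospore counts per pretreatment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

from .types import RelAbundanceTable, ValidationError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "AnosimResult",
    "richness",
    "chao1",
    "inverse_simpson",
    "alpha_diversity_table",
    "bray_curtis",
    "bray_curtis_matrix",
    "nmds",
    "nmds_stress",
    "anosim",
    "kruskal_wallis",
]


def _counts_vector(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValidationError("counts must be non-negative")
    return x


def richness(counts) -> int:
    """Number of OTUs with at least one read."""
    return int(np.count_nonzero(_counts_vector(counts) > 0))


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate (defined even when F2=0)."""
    x = _counts_vector(counts)
    if x.size and not np.array_equal(x, np.rint(x)):
        raise ValidationError("Chao1 requires integer counts")
    s_obs = np.count_nonzero(x > 0)
    f1 = int(np.count_nonzero(x == 1))
    f2 = int(np.count_nonzero(x == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def inverse_simpson(fractions) -> float:
    """Effective number of taxa 1 / sum(p^2)."""
    p = np.asarray(fractions, dtype=float)
    if (p < 0).any():
        raise ValidationError("fractions must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValidationError("cannot compute evenness of an empty community")
    p = p / total
    return float(1.0 / np.sum(p * p))


def alpha_diversity_table(table) -> pd.DataFrame:
    """Richness, Chao1 and inverse Simpson per sample of a count table."""
    rows = {}
    for sample in table.sample_ids:
        c = table.counts[sample].to_numpy()
        rows[sample] = {
            "richness": richness(c),
            "chao1": chao1(c),
            "inverse_simpson": inverse_simpson(c),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(x, y) -> float:
    """sum|x-y| / sum(x+y) between two non-negative vectors."""
    x = _counts_vector(x)
    y = _counts_vector(y)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two empty communities")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(rel: RelAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between samples (columns)."""
    data = rel.fractions.to_numpy().T  # samples x OTUs
    if (data.sum(axis=1) == 0).any():
        raise ValidationError("every sample must have positive total abundance")
    condensed = pdist(data, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=rel.sample_ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float
    n_iterations: int
    converged: bool
    seed: int


def _disparities(
    condensed_d: np.ndarray, order: np.ndarray, zero_mask: np.ndarray
) -> np.ndarray:
    """Monotone (PAV) regression of configuration distances on the
    rank order of the input dissimilarities.

    Pairs whose input dissimilarity is exactly zero (identical samples)
    get a zero disparity, so the stress actively pulls them together
    rather than merely keeping them first in rank order."""
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(len(order)), condensed_d[order])
    dhat = np.empty_like(condensed_d)
    dhat[order] = fitted
    dhat[zero_mask] = 0.0
    return dhat


def _stress1(condensed_d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(condensed_d**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((condensed_d - dhat) ** 2) / denom))


def nmds_stress(dm: DistanceMatrix, coordinates) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    delta = squareform(np.asarray(dm.data), checks=False)
    x = np.asarray(coordinates, dtype=float)
    d = pdist(x)
    order = np.argsort(delta, kind="stable")
    return _stress1(d, _disparities(d, order, delta == 0))


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS by direct stress-1 descent.

    Each start draws a uniform configuration in [-1, 1]^k and alternates
    pool-adjacent-violators disparities with a gradient step on stress,
    halving the step until stress decreases; the best of ``n_starts`` runs
    is returned with centered coordinates.
    """
    delta = squareform(np.asarray(dm.data), checks=False)
    n = len(dm.ids)
    if k < 1 or k >= n:
        raise ValidationError(f"embedding dimension k={k} must satisfy 1 <= k < {n}")
    order = np.argsort(delta, kind="stable")
    zero_mask = delta == 0
    iu = np.triu_indices(n, 1)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_starts):
        x = rng.uniform(-1.0, 1.0, size=(n, k))
        d = pdist(x)
        dhat = _disparities(d, order, zero_mask)
        stress = _stress1(d, dhat)
        step = 0.1
        it = 0
        converged = False
        while it < max_iter:
            it += 1
            # gradient of the raw stress numerator w.r.t. coordinates
            diff = np.zeros_like(d)
            nz = d > 1e-12
            diff[nz] = (d[nz] - dhat[nz]) / d[nz]
            g = np.zeros_like(x)
            full = np.zeros((n, n))
            full[iu] = diff
            full += full.T
            # grad_i = 2 * sum_j diff_ij * (x_i - x_j)
            g = 2.0 * (full.sum(axis=1)[:, None] * x - full @ x)
            gnorm = np.linalg.norm(g)
            if gnorm == 0:
                converged = True
                break
            improved = False
            while step > 1e-14:
                x_new = x - step * g / gnorm
                d_new = pdist(x_new)
                dhat_new = _disparities(d_new, order, zero_mask)
                s_new = _stress1(d_new, dhat_new)
                if s_new < stress:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                converged = True
                break
            gain = stress - s_new
            x, d, dhat, stress = x_new, d_new, dhat_new, s_new
            step *= 1.5
            if gain < tol:
                converged = True
                break
        if best is None or stress < best[0]:
            best = (stress, x, it, converged)

    stress, x, it, converged = best
    x = x - x.mean(axis=0)
    coords = pd.DataFrame(
        x, index=list(dm.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coords, float(stress), it, converged, seed)


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int
    seed: int


def anosim(
    dm: DistanceMatrix,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) over
    the M = n(n-1)/2 pairwise distances, with mid-ranks for ties. The
    permutation p-value includes the observed statistic in the tally.
    """
    labels = np.asarray(groups)
    n = len(dm.ids)
    if len(labels) != n:
        raise ValidationError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 members")

    condensed = squareform(np.asarray(dm.data), checks=False)
    ranks = scipy.stats.rankdata(condensed)
    m = len(condensed)
    iu, ju = np.triu_indices(n, 1)

    def _r(lbls: np.ndarray) -> float:
        within = lbls[iu] == lbls[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = _r(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _r(rng.permutation(labels)) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return AnosimResult(float(r_obs), float(p), n_permutations, seed)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H and chi-square p-value with tie correction.

    By convention, fully degenerate data (every value identical across
    all groups) gives H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("groups must be non-empty")
    if sum(len(a) for a in arrays) < 3:
        raise ValidationError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    stat, p = scipy.stats.kruskal(*arrays)
    return float(stat), float(p)
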