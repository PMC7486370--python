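"""Ordination, correlation and paired-test machinery.

Bray–Curtis dissimilarity with classical-scaling PCoA for community
ordination, group-level Spearman/Pearson correlation reports, and an exact
Wilcoxon signed-rank test (full null enumeration for small n, as the paired
within-subject design of gut-location comparisons has n of only a handful).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr
from skbio.stats.distance import DistanceMatrix

from .mgs import SampleMetadata
from .quantify import AbundanceMatrix

__all__ = [
    "CorrelationReport",
    "PCoAResult",
    "bray_curtis",
    "pcoa",
    "group_means",
    "group_spearman",
    "genus_scatter_r2",
    "wilcoxon_signed_rank",
]


@dataclass
class CorrelationReport:
    group_a: str
    group_b: str
    spearman_rho: float | None
    pearson_r2: float | None
    n_features: int
    features: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives incl.)
    negative_inertia_fraction: float


def bray_curtis(matrix: AbundanceMatrix) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity between samples.

    BC(i, j) = 1 - 2 * sum(min(x_i, x_j)) / (sum x_i + sum x_j); 0 for
    identical samples, 1 for disjoint supports. Undefined between two
    all-zero samples, which is rejected.
    """
    X = matrix.values.to_numpy(dtype=float).T
    if (X < 0).any():
        raise ValueError("Bray-Curtis needs non-negative abundances")
    zero = X.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(matrix.samples, zero) if z]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids=matrix.samples)


def pcoa(d: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Principal coordinates analysis (classical / Torgerson scaling).

    Double-centres -D^2/2, eigendecomposes, and returns coordinates for the
    top-k positive eigenvalues (axes scaled by sqrt(eigenvalue), sign
    arbitrary per axis). Negative eigenvalues — expected for semimetrics
    like Bray–Curtis — are reported and their axes dropped.
    """
    D = d.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals).max(), 1.0) * 1e-12
    n_pos = int((evals > tol).sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; "
            "returning the truncated set", stacklevel=2)
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    neg = float(-evals[evals < 0].sum())
    total = float(np.abs(evals).sum())
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=list(d.ids),
            columns=[f"PCo{i + 1}" for i in range(k)]),
        eigenvalues=evals,
        negative_inertia_fraction=neg / total if total > 0 else 0.0,
    )


def group_means(matrix: AbundanceMatrix, metadata: SampleMetadata,
                group: str) -> pd.Series:
    """Mean abundance per feature over a location group's samples."""
    return matrix.values[metadata.samples(group)].mean(axis=1)


def group_spearman(matrix: AbundanceMatrix, metadata: SampleMetadata,
                   group_a: str, group_b: str) -> CorrelationReport:
    """Spearman rank correlation of group-mean abundances over shared features.

    Features must be detected (mean > 0) in both groups; ties are mid-ranked.
    """
    ma, mb = group_means(matrix, metadata, group_a), group_means(matrix, metadata, group_b)
    shared = list(ma.index[(ma > 0) & (mb > 0)])
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} features shared by {group_a!r} and {group_b!r};"
            " need >= 3")
    rho = float(spearmanr(ma[shared], mb[shared]).statistic)
    return CorrelationReport(group_a, group_b, spearman_rho=rho,
                             pearson_r2=None, n_features=len(shared),
                             features=shared)


def genus_scatter_r2(matrix: AbundanceMatrix, metadata: SampleMetadata,
                     group_a: str, group_b: str,
                     exclude: list[str] | None = None
                     ) -> tuple[CorrelationReport, CorrelationReport]:
    """Pearson r² of group-mean abundances, with and without excluded taxa.

    Mirrors the faeces-vs-biopsies genus scatter where one dominant,
    location-enriched genus (Bacteroides-like) depresses the correlation and
    its removal raises it. Returns (report_all, report_excluding).
    """
    exclude = list(exclude or [])
    ma, mb = group_means(matrix, metadata, group_a), group_means(matrix, metadata, group_b)
    shared = list(ma.index[(ma > 0) & (mb > 0)])
    if len(shared) < 3:
        raise ValueError("need >= 3 shared taxa")

    def _r2(feats: list[str]) -> float:
        return float(pearsonr(ma[feats], mb[feats]).statistic ** 2)

    kept = [f for f in shared if f not in exclude]
    if len(kept) < 3:
        raise ValueError("exclusion leaves < 3 shared taxa")
    rep_all = CorrelationReport(group_a, group_b, spearman_rho=None,
                                pearson_r2=_r2(shared),
                                n_features=len(shared), features=shared)
    rep_excl = CorrelationReport(group_a, group_b, spearman_rho=None,
                                 pearson_r2=_r2(kept), n_features=len(kept),
                                 features=kept,
                                 excluded=[f for f in shared if f in exclude])
    return rep_all, rep_excl


def _signed_rank_stat(diff: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ and the midranks of |diff| (zeros must be removed already)."""
    ranks = pd.Series(np.abs(diff)).rank(method="average").to_numpy()
    w_plus = float(ranks[diff > 0].sum())
    return w_plus, ranks


def _exact_tail_probs(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all 2^n sign assignments, via DP on rank sums.

    Midranks can be half-integers; doubling makes all sums integers so the
    distribution of 2*W+ is a convolution of {0, 2r_i} point masses.
    """
    r2 = np.rint(ranks * 2).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    lo = min(w2, total - w2)
    hi = total - lo
    p = float(dist[: lo + 1].sum() + dist[hi:].sum())
    return min(p, 1.0)


def wilcoxon_signed_rank(x, y, *, exact_max_n: int = 25) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W+, two-sided p).

    Zero differences are dropped (Wilcoxon's rule). For n <= ``exact_max_n``
    informative pairs the p-value is exact over the full null distribution of
    sign assignments (ties handled by midranks); beyond that, a normal
    approximation with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    diff = x - y
    diff = diff[diff != 0]
    n = len(diff)
    if n == 0:
        raise ValueError("no informative pairs: all differences are zero")
    w_plus, ranks = _signed_rank_stat(diff)
    if n <= exact_max_n:
        return w_plus, _exact_tail_probs(ranks, w_plus)
    # normal approximation with tie correction
    mu = n * (n + 1) / 4.0
    tie_term = 0.0
    for _, cnt in pd.Series(ranks).value_counts().items():
        tie_term += cnt ** 3 - cnt
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0)
    from scipy.stats import norm
    z = (w_plus - mu) / sigma
    return w_plus, float(min(1.0, 2.0 * norm.sf(abs(z))))
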