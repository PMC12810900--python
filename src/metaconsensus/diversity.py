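"""Alpha/beta diversity, age trends, and cross-classifier concordance tests.

Alpha diversity is summarized as Pielou's evenness (Shannon entropy divided
by the log of richness), a normalized score in [0, 1] describing the
heterogeneity of a sample's relative abundances.  Community-level structure
uses Bray-Curtis dissimilarity, principal coordinate analysis, and
distance-based PERMANOVA against a continuous covariate; agreement between
two classifiers' views of the same samples is quantified with symmetric
Procrustes superposition and the Mantel test, both with permutation
p-values.

All permutation tests take an explicit seed, report
``p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm)``, and can enumerate
every permutation exactly for small sample counts (``exact=True``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from .profiles import TaxonProfile

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "TrendResult",
    "ConcordanceResult",
    "normalized_alpha",
    "richness",
    "alpha_diversity_table",
    "age_trend",
    "bray_curtis",
    "pcoa",
    "permanova",
    "procrustes_test",
    "mantel_test",
    "pearson_concordance",
]

_MAX_EXACT_N = 9  # 9! = 362880 permutations; enumeration above this is refused


@dataclass
class TrendResult:
    """OLS slope of a diversity score on age (years), with two-sided p."""

    slope: float
    intercept: float
    p_value: float
    n: int


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("ids do not match matrix dimension")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding: samples x axes, ordered by eigenvalue."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def ids(self) -> list[str]:
        return list(self.coordinates.index)


@dataclass
class ConcordanceResult:
    """A concordance statistic with its permutation p-value."""

    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int


def normalized_alpha(abundances) -> float:
    """Pielou evenness H / ln(S) of a relative-abundance vector.

    H is Shannon entropy over the nonzero fractions (renormalized
    internally), S the number of nonzero taxa.  Bounded in [0, 1]; a
    single-taxon sample scores 0 by convention.  Invariant to rescaling of
    the abundance vector.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = x[x > 0] / total
    s = p.size
    if s == 1:
        return 0.0
    h = float(-(p * np.log(p)).sum())
    return h / math.log(s)


def richness(abundances) -> int:
    """Count of taxa with strictly positive abundance."""
    x = np.asarray(abundances, dtype=float)
    return int((x > 0).sum())


def alpha_diversity_table(profile: TaxonProfile) -> pd.DataFrame:
    """Per-sample normalized alpha diversity and richness for one profile."""
    rows = []
    for sample in profile.samples:
        col = profile.data[sample].to_numpy()
        rows.append(
            {
                "sample": sample,
                "classifier": profile.classifier_label,
                "level": profile.level,
                "normalized_alpha": normalized_alpha(col),
                "richness": richness(col),
            }
        )
    return pd.DataFrame(rows)


def age_trend(scores, ages) -> TrendResult:
    """Ordinary least-squares trend of a per-sample score on age."""
    y = np.asarray(scores, dtype=float)
    x = np.asarray(ages, dtype=float)
    if y.shape != x.shape:
        raise ValueError("scores and ages must have matching length")
    if y.size < 3:
        raise ValueError("need at least 3 samples for a trend test")
    if np.ptp(x) == 0:
        raise ValueError("age vector is constant")
    if np.ptp(y) == 0:
        return TrendResult(slope=0.0, intercept=float(y[0]), p_value=1.0, n=y.size)
    fit = stats.linregress(x, y)
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=y.size,
    )


def bray_curtis(profile: TaxonProfile) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs of a profile."""
    matrix = profile.data.to_numpy(dtype=float).T  # samples x taxa
    totals = matrix.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(profile.samples, totals) if t <= 0]
        raise ValueError(f"samples with zero total abundance: {bad}")
    condensed = pdist(matrix, metric="braycurtis")
    return DistanceMatrix(ids=profile.samples, values=squareform(condensed))


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling of a dissimilarity matrix.

    Eigendecomposes the Gower-centered matrix and keeps the positive
    eigenvalues; variance fractions are reported over the positive
    eigenvalues only (negative eigenvalues from non-Euclidean
    dissimilarities are discarded without correction).
    """
    if d.n < 3:
        raise ValueError("need at least 3 samples for ordination")
    b = _gower_center(d.values)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    eigvals, eigvecs = eigvals[positive], eigvecs[:, positive]
    if n_axes is not None:
        eigvals, eigvecs = eigvals[:n_axes], eigvecs[:, :n_axes]
    coords = eigvecs * np.sqrt(eigvals)
    frame = pd.DataFrame(
        coords,
        index=d.ids,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    total = eigvals.sum()
    proportion = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return OrdinationResult(
        coordinates=frame, eigenvalues=eigvals, proportion_explained=proportion
    )


def _permutations(n: int, n_perm: int, seed, exact: bool):
    if exact:
        if n > _MAX_EXACT_N:
            raise ValueError(f"exact enumeration limited to n <= {_MAX_EXACT_N}")
        return list(itertools.permutations(range(n))), True
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    rng = np.random.default_rng(seed)
    return [rng.permutation(n) for _ in range(n_perm)], False


def _perm_pvalue(stat_obs: float, stat_perm: np.ndarray, exact: bool) -> float:
    hits = int(np.sum(stat_perm >= stat_obs - 1e-12))
    if exact:
        # enumeration includes the identity permutation
        return hits / stat_perm.size
    return (1 + hits) / (1 + stat_perm.size)


def _pseudo_f(g: np.ndarray, x: np.ndarray) -> float:
    """Distance-based pseudo-F for a design matrix x (with intercept)."""
    n = g.shape[0]
    q = x.shape[1] - 1
    h = x @ np.linalg.solve(x.T @ x, x.T)
    i_h = np.eye(n) - h
    num = np.trace(h @ g @ h) / q
    den = np.trace(i_h @ g @ i_h) / (n - q - 1)
    return num / den


def permanova(
    d: DistanceMatrix,
    covariate,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> ConcordanceResult:
    """Distance-based multivariate regression on a continuous covariate.

    Partitions the Gower-centered dissimilarity matrix against the
    covariate (pseudo-F) and assesses significance by permuting the
    covariate across samples.
    """
    x = np.asarray(covariate, dtype=float)
    if x.size != d.n:
        raise ValueError("covariate length must match distance matrix")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    g = _gower_center(d.values)
    design = np.column_stack([np.ones(d.n), x])
    f_obs = _pseudo_f(g, design)
    perms, is_exact = _permutations(d.n, n_perm, seed, exact)
    f_perm = np.array(
        [_pseudo_f(g, np.column_stack([np.ones(d.n), x[list(p)]])) for p in perms]
    )
    return ConcordanceResult(
        statistic_name="pseudo-F",
        statistic=float(f_obs),
        p_value=_perm_pvalue(f_obs, f_perm, is_exact),
        n_permutations=len(perms),
    )


def _procrustes_corr(a: np.ndarray, b: np.ndarray) -> float:
    _, _, m2 = _scipy_procrustes(a, b)
    return math.sqrt(max(0.0, 1.0 - m2))


def _shared_axes(a: "OrdinationResult", b: "OrdinationResult"):
    if a.ids != b.ids:
        raise ValueError("ordinations must cover the same samples in the same order")
    k = min(a.coordinates.shape[1], b.coordinates.shape[1])
    if k < 1:
        raise ValueError("ordinations have no axes")
    return (
        a.coordinates.to_numpy()[:, :k].copy(),
        b.coordinates.to_numpy()[:, :k].copy(),
    )


def procrustes_test(
    a: OrdinationResult,
    b: OrdinationResult,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> ConcordanceResult:
    """Symmetric Procrustes concordance of two ordinations of the same samples.

    Both configurations are centered and scaled to unit norm before the
    optimal rotation; the statistic is sqrt(1 - m2) where m2 is the residual
    sum of squares.  The permutation null shuffles the rows of the second
    configuration.
    """
    ca, cb = _shared_axes(a, b)
    stat_obs = _procrustes_corr(ca, cb)
    perms, is_exact = _permutations(len(a.ids), n_perm, seed, exact)
    stat_perm = np.array([_procrustes_corr(ca, cb[list(p), :]) for p in perms])
    return ConcordanceResult(
        statistic_name="procrustes_r",
        statistic=float(stat_obs),
        p_value=_perm_pvalue(stat_obs, stat_perm, is_exact),
        n_permutations=len(perms),
    )


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> ConcordanceResult:
    """Mantel correlation between two distance matrices over the same samples.

    Pearson correlation of the off-diagonal entries; the permutation null
    applies a simultaneous row/column permutation to the first matrix.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must cover the same samples in order")
    v1, v2 = d1.condensed(), d2.condensed()
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("constant distances; Mantel correlation undefined")
    stat_obs = float(np.corrcoef(v1, v2)[0, 1])
    perms, is_exact = _permutations(d1.n, n_perm, seed, exact)
    full1 = d1.values
    stat_perm = np.empty(len(perms))
    for i, p in enumerate(perms):
        idx = list(p)
        permuted = full1[np.ix_(idx, idx)]
        stat_perm[i] = np.corrcoef(squareform(permuted, checks=False), v2)[0, 1]
    return ConcordanceResult(
        statistic_name="mantel_r",
        statistic=stat_obs,
        p_value=_perm_pvalue(stat_obs, stat_perm, is_exact),
        n_permutations=len(perms),
    )


def pearson_concordance(x, y) -> ConcordanceResult:
    """Pearson correlation of two per-sample score vectors (parametric p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("score vectors must have matching length")
    r, p = stats.pearsonr(x, y)
    return ConcordanceResult(
        statistic_name="pearson_r",
        statistic=float(r),
        p_value=float(p),
        n_permutations=0,
    )
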