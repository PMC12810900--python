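"""AdjMaxP correlated meta-analysis and comparator p-value combiners.

Two association scans of the same samples — e.g. differential-abundance
tests run on profiles from two taxonomic classifiers — produce dependent
per-feature p-values.  For independent studies, the probability that a
feature's p-value is at most ``max(p_a, p_b)`` in *both* studies is
``max(p_a, p_b)**2``, so the maximum p-value raised to the number of
studies is itself a valid combined p-value that rewards conserved signal.
AdjMaxP generalizes this to dependent studies by replacing the exponent
with an *effective number of studies* ``k_eff in [1, k]``, derived from the
tetrachoric correlation between the probit-transformed p-value vectors:

    combined_p = max(p_a, p_b) ** k_eff,   k_eff = k - (k - 1) * max(r_t, 0)

At ``r_t = 0`` this is the exact independent orthant probability; as
``r_t -> 1`` (fully redundant studies) it degenerates to the single-study
p-value.

Also provided: the Province-Borecki combiner (a Fisher-type statistic
referred to a scaled chi-square null with a Brown-style covariance
adjustment) and a naive concordance rule (significant in both studies with
matching effect direction), used as benchmark comparators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .diffabund import bh_fdr
from .profiles import normalize_taxon_name

__all__ = [
    "P_MIN",
    "probit",
    "tetrachoric_r",
    "effective_k",
    "adjmaxp_combine",
    "province_borecki_combine",
    "naive_concordance",
    "harmonize",
]

# p-values are clamped away from {0, 1} before probit/log transforms
P_MIN = 1e-15
_R_MAX = 0.999


def _clamp_p(p) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), P_MIN, 1.0 - P_MIN)


def probit(p) -> np.ndarray:
    """Standard-normal quantile of p, clamped to (1e-15, 1 - 1e-15)."""
    return stats.norm.ppf(_clamp_p(p))


def _bvn_survival(h: float, k: float, r: float) -> float:
    """P(Z1 > h, Z2 > k) for standard bivariate normal with correlation r."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
    return 1.0 - stats.norm.cdf(h) - stats.norm.cdf(k) + float(mvn.cdf([h, k]))


def tetrachoric_r(p_a, p_b, threshold: float = 0.5) -> float:
    """Maximum-likelihood tetrachoric correlation of two paired p-value sets.

    Each vector is dichotomized at ``threshold`` (the probit-scale median by
    default) and the latent bivariate-normal correlation is fitted to the
    resulting 2x2 concordance table, with thresholds fixed at the observed
    marginals.  The estimate is clamped to [-0.999, 0.999].
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape or p_a.ndim != 1:
        raise ValueError("paired p-value vectors must be 1-D and equal length")
    n = p_a.size
    if n < 20:
        warnings.warn(
            f"tetrachoric correlation estimated from only {n} pairs; "
            "estimates are unstable below ~20",
            stacklevel=2,
        )
    u = p_a > threshold
    v = p_b > threshold
    pu, pv = u.mean(), v.mean()
    if pu in (0.0, 1.0) or pv in (0.0, 1.0):
        raise ValueError(
            "a margin lies entirely on one side of the threshold; "
            "tetrachoric correlation is unidentifiable"
        )
    p11 = np.mean(u & v)
    h = stats.norm.ppf(1.0 - pu)
    k = stats.norm.ppf(1.0 - pv)

    def gap(r: float) -> float:
        return _bvn_survival(h, k, r) - p11

    lo, hi = gap(-_R_MAX), gap(_R_MAX)
    if lo > 0:  # observed concordance below what r = -0.999 allows
        return -_R_MAX
    if hi < 0:  # observed concordance above what r = 0.999 allows
        return _R_MAX
    return float(optimize.brentq(gap, -_R_MAX, _R_MAX, xtol=1e-10))


def effective_k(
    r_t: float, k: int = 2, rule: str = "calibrated", alpha: float = 0.05
) -> float:
    """Effective number of studies under cross-study correlation ``r_t``.

    Both rules equal ``k`` for uncorrelated studies and approach 1 as the
    studies become fully redundant; negative correlations are truncated to
    0 so the exponent never exceeds ``k``.

    ``rule="calibrated"`` (default, two studies): the exponent solves the
    latent bivariate-normal orthant equation at the reference level
    ``alpha`` — ``P(Z1 > c, Z2 > c; r_t) = alpha`` with
    ``c = Phi^-1(1 - alpha**(1/k_eff))`` — so that a combined p-value of
    ``alpha`` corresponds exactly to the dependent-orthant tail
    probability.  This keeps the type-I error of thresholding the combined
    p at ``alpha`` exact under the latent Gaussian model.

    ``rule="linear"``: the interpolation ``k - (k - 1) * max(r_t, 0)``, a
    simpler approximation that is mildly anticonservative at small
    positive correlations.  Always used when ``k > 2``.
    """
    if k < 1:
        raise ValueError("number of studies must be >= 1")
    if not -1.0 <= r_t <= 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    if rule not in ("calibrated", "linear"):
        raise ValueError("rule must be 'calibrated' or 'linear'")
    if rule == "linear" or k != 2:
        return float(max(1.0, k - (k - 1) * max(r_t, 0.0)))
    r = min(max(r_t, 0.0), _R_MAX)
    if r < 1e-6:
        return float(k)

    def gap(k_eff: float) -> float:
        c = stats.norm.ppf(1.0 - alpha ** (1.0 / k_eff))
        return _bvn_survival(c, c, r) - alpha

    # gap(1) = orthant(alpha-threshold) - alpha < 0 for r < 1;
    # gap(2) = orthant(sqrt(alpha)-threshold) - alpha >= 0 for r >= 0
    lo, hi = gap(1.0), gap(2.0)
    if hi <= 0.0:  # numerical noise at tiny r
        return 2.0
    if lo >= 0.0:  # numerical noise at r near 1
        return 1.0
    return float(optimize.brentq(gap, 1.0, 2.0, xtol=1e-8))


def adjmaxp_combine(p_a, p_b, k_eff: float):
    """Combined p-value ``max(p_a, p_b) ** k_eff`` (vectorized)."""
    if not 1.0 <= k_eff:
        raise ValueError("k_eff must be >= 1")
    pa = _clamp_p(p_a)
    pb = _clamp_p(p_b)
    out = np.maximum(pa, pb) ** k_eff
    if np.isscalar(p_a) and np.isscalar(p_b):
        return float(out)
    return out


def _brown_covariance(r: float) -> float:
    # polynomial approximation to cov(-2 ln p_1, -2 ln p_2) for test
    # statistics with correlation r >= 0
    r = max(r, 0.0)
    return r * (3.263 + 0.710 * r + 0.027 * r**2)


def province_borecki_combine(p_a, p_b, r_t: float):
    """Correlation-adjusted Fisher combination of two dependent p-values.

    ``X = -2 (ln p_a + ln p_b)`` is referred to a scaled chi-square
    ``c * chi2_f`` matching the first two moments of the dependent null:
    ``E[X] = 2k`` and ``Var[X] = 4k + 2 cov``, with the covariance taken
    from Brown's polynomial in ``r_t``.  At ``r_t = 0`` this is exactly
    Fisher's method with 2k degrees of freedom.
    """
    pa = _clamp_p(p_a)
    pb = _clamp_p(p_b)
    x = -2.0 * (np.log(pa) + np.log(pb))
    k = 2
    mean = 2.0 * k
    var = 4.0 * k + 2.0 * _brown_covariance(r_t)
    c = var / (2.0 * mean)
    f = 2.0 * mean**2 / var
    out = stats.chi2.sf(x / c, f)
    if np.isscalar(p_a) and np.isscalar(p_b):
        return float(out)
    return out


def naive_concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    alpha: float = 0.05,
    use: str = "q",
) -> pd.Series:
    """Concordance calls: significant in both tables with matching sign.

    ``use='q'`` thresholds FDR q-values (the usual discovery rule);
    ``use='p'`` thresholds nominal p-values (for type-I evaluation).
    Features with a missing or zero effect sign are flagged False with a
    warning.  Indexed by the shared features.
    """
    if use not in ("p", "q"):
        raise ValueError("use must be 'p' or 'q'")
    shared = results_a.index.intersection(results_b.index)
    a = results_a.loc[shared]
    b = results_b.loc[shared]
    sig = (a[use] < alpha).to_numpy() & (b[use] < alpha).to_numpy()
    sign_a = np.sign(a["estimate"].to_numpy(dtype=float))
    sign_b = np.sign(b["estimate"].to_numpy(dtype=float))
    defined = (sign_a != 0) & (sign_b != 0) & np.isfinite(sign_a) & np.isfinite(sign_b)
    if (~defined & sig).any():
        warnings.warn(
            "features with undefined effect sign flagged non-concordant",
            stacklevel=2,
        )
    flags = sig & defined & (sign_a == sign_b)
    return pd.Series(flags, index=shared, name="concordant")


@dataclass
class MetaTable:
    """Harmonized cross-classifier meta-analysis results.

    ``table`` has one row per feature in the union of the two association
    tables, with the combined p-value, mean effect estimate, the tetrachoric
    correlation and effective study count used, BH FDR over the combined
    p-values, and whether the row came from the meta-analysis or a single
    classifier.
    """

    table: pd.DataFrame
    r_t: float | None
    k_eff: float | None

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t")


def harmonize(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    r_t: float | None = None,
    dichotomize_at: float = 0.5,
    keff_rule: str = "calibrated",
) -> MetaTable:
    """Combine two classifiers' association tables into one meta-table.

    Features are aligned by normalized taxon name.  Shared features receive
    the AdjMaxP combined p-value, with a single tetrachoric correlation
    estimated from all shared features (or supplied via ``r_t``), and the
    unweighted mean of the two effect estimates (the two scans cover the
    same samples, so neither carries more weight).  Features seen by one
    classifier keep that classifier's p-value and estimate.  BH FDR is
    computed over the combined p-values of the whole union.
    """
    a = results_a.copy()
    b = results_b.copy()
    a.index = a.index.astype(str)
    b.index = b.index.astype(str)

    norm_b: dict[str, str] = {}
    for name in b.index:
        norm_b.setdefault(normalize_taxon_name(name), name)
    pairs: list[tuple[str, str]] = []
    only_a: list[str] = []
    matched_b: set[str] = set()
    for name in a.index:
        target = norm_b.get(normalize_taxon_name(name))
        if target is not None and target not in matched_b:
            pairs.append((name, target))
            matched_b.add(target)
        else:
            only_a.append(name)
    only_b = [n for n in b.index if n not in matched_b]

    rows: list[dict] = []
    est_rt: float | None = r_t
    keff: float | None = None
    if pairs:
        pa = a.loc[[x for x, _ in pairs], "p"].to_numpy(dtype=float)
        pb = b.loc[[y for _, y in pairs], "p"].to_numpy(dtype=float)
        if est_rt is None:
            if len(pairs) >= 2:
                try:
                    est_rt = tetrachoric_r(pa, pb, threshold=dichotomize_at)
                except ValueError:
                    warnings.warn(
                        "tetrachoric correlation unidentifiable; assuming "
                        "independent classifiers (r_t = 0)",
                        stacklevel=2,
                    )
                    est_rt = 0.0
            else:
                est_rt = 0.0
        keff = effective_k(est_rt, k=2, rule=keff_rule)
        combined = adjmaxp_combine(pa, pb, keff)
        ea = a.loc[[x for x, _ in pairs], "estimate"].to_numpy(dtype=float)
        eb = b.loc[[y for _, y in pairs], "estimate"].to_numpy(dtype=float)
        for i, (name_a, name_b) in enumerate(pairs):
            rows.append(
                {
                    "feature": name_a,
                    "p_a": pa[i],
                    "p_b": pb[i],
                    "effect_a": ea[i],
                    "effect_b": eb[i],
                    "r_t": est_rt,
                    "k_eff": keff,
                    "combined_p": combined[i],
                    "combined_estimate": (ea[i] + eb[i]) / 2.0,
                    "sign_concordant": bool(np.sign(ea[i]) == np.sign(eb[i])),
                    "source": "meta",
                }
            )
    else:
        warnings.warn(
            "no shared features between the two tables; falling back to "
            "single-classifier p-values throughout",
            stacklevel=2,
        )

    for name in only_a:
        rows.append(
            {
                "feature": name,
                "p_a": float(a.loc[name, "p"]),
                "p_b": np.nan,
                "effect_a": float(a.loc[name, "estimate"]),
                "effect_b": np.nan,
                "r_t": np.nan,
                "k_eff": np.nan,
                "combined_p": float(a.loc[name, "p"]),
                "combined_estimate": float(a.loc[name, "estimate"]),
                "sign_concordant": np.nan,
                "source": "single_a",
            }
        )
    for name in only_b:
        rows.append(
            {
                "feature": name,
                "p_a": np.nan,
                "p_b": float(b.loc[name, "p"]),
                "effect_a": np.nan,
                "effect_b": float(b.loc[name, "estimate"]),
                "r_t": np.nan,
                "k_eff": np.nan,
                "combined_p": float(b.loc[name, "p"]),
                "combined_estimate": float(b.loc[name, "estimate"]),
                "sign_concordant": np.nan,
                "source": "single_b",
            }
        )

    table = pd.DataFrame(rows).set_index("feature")
    table["combined_q"] = bh_fdr(np.clip(table["combined_p"].to_numpy(), 0.0, 1.0))
    return MetaTable(table=table, r_t=est_rt, k_eff=keff)
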