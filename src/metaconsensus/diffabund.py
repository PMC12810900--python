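"""Per-taxon differential abundance with age.

Relative abundances are log-transformed with a matrix-wide pseudocount and
each taxon is regressed on age with sex and education as covariates.  When
the metadata carries family clusters (e.g. centenarian-offspring pairs),
the fit uses generalized estimating equations with an exchangeable working
correlation and robust (sandwich) standard errors; when every cluster has
size one this degenerates to OLS with heteroskedasticity-robust errors.
P-values across taxa are corrected with Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .profiles import TaxonProfile

__all__ = [
    "log_transform",
    "default_pseudocount",
    "fit_taxon_model",
    "differential_abundance",
    "bh_fdr",
    "TaxonFit",
]


class TaxonFit(NamedTuple):
    estimate: float
    se: float
    p_value: float


def default_pseudocount(matrix: np.ndarray) -> float:
    """Half the smallest nonzero abundance in the matrix."""
    nonzero = matrix[matrix > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero abundance matrix")
    return float(nonzero.min()) / 2.0


def log_transform(
    profile: TaxonProfile, pseudocount: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Natural log of (abundance + pseudocount); returns (matrix, pseudocount).

    The default pseudocount is half the smallest nonzero abundance in the
    whole matrix, so zeros map to a common floor value below every observed
    abundance.
    """
    values = profile.data.to_numpy(dtype=float)
    if pseudocount is None:
        pseudocount = default_pseudocount(values)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return pd.DataFrame(
        np.log(values + pseudocount), index=profile.data.index, columns=profile.data.columns
    ), pseudocount


_REQUIRED_META = ("age",)


def _build_design(
    meta: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    for col in _REQUIRED_META:
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if (meta["age"] <= 0).any():
        raise ValueError("ages must be positive")
    columns: dict[str, np.ndarray] = {"intercept": np.ones(len(meta))}
    columns["age"] = meta["age"].to_numpy(dtype=float)
    for cov in covariates:
        if cov not in meta.columns:
            raise ValueError(f"metadata missing covariate column {cov!r}")
        series = meta[cov]
        if series.nunique() < 2:
            raise ValueError(f"covariate columns with zero variance: ['{cov}']")
        if pd.api.types.is_numeric_dtype(series):
            columns[cov] = series.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                columns[name] = dummies[name].to_numpy(dtype=float)
    names = list(columns)
    x = np.column_stack([columns[n] for n in names])
    # zero-variance covariate columns are an input defect, not something to
    # drop silently
    variances = x[:, 1:].var(axis=0)
    degenerate = [names[i + 1] for i in np.flatnonzero(variances == 0)]
    if degenerate:
        raise ValueError(f"covariate columns with zero variance: {degenerate}")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        corr = np.corrcoef(x[:, 1:], rowvar=False)
        collinear = sorted(
            {
                names[i + 1]
                for i in range(corr.shape[0])
                for j in range(corr.shape[0])
                if i != j and abs(corr[i, j]) > 1 - 1e-10
            }
        ) or names[1:]
        raise ValueError(f"singular design matrix; collinear columns: {collinear}")
    return x, names


def fit_taxon_model(
    y,
    meta: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "education"),
    cluster: str | None = "family_id",
) -> TaxonFit:
    """Age coefficient for one taxon's log abundance.

    Returns (estimate, robust SE, two-sided p) for the per-year age effect.
    With ``cluster`` set and clusters of size > 1 present, fits a Gaussian
    GEE with exchangeable working correlation; otherwise OLS with HC0
    sandwich errors.  A constant response returns (0, 0, 1) by convention.
    """
    y = np.asarray(y, dtype=float)
    if y.size != len(meta):
        raise ValueError("response length does not match metadata")
    if y.size < 10:
        raise ValueError("need at least 10 samples")
    if meta["age"].nunique() < 2:
        raise ValueError("need at least 2 distinct ages")
    if np.ptp(y) == 0:
        return TaxonFit(estimate=0.0, se=0.0, p_value=1.0)

    x, names = _build_design(meta, covariates)
    age_idx = names.index("age")

    groups = None
    if cluster is not None and cluster in meta.columns:
        groups = meta[cluster].to_numpy()
    if groups is not None and pd.Series(groups).value_counts().max() > 1:
        model = sm.GEE(
            y,
            x,
            groups=groups,
            family=sm.families.Gaussian(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit()
    else:
        result = sm.OLS(y, x).fit(cov_type="HC0")
    return TaxonFit(
        estimate=float(result.params[age_idx]),
        se=float(result.bse[age_idx]),
        p_value=float(result.pvalues[age_idx]),
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-equivariant)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(
    profile: TaxonProfile,
    metadata: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "education"),
    cluster: str | None = "family_id",
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-taxon age association table for one classifier's profile.

    Returns a DataFrame indexed by taxon with columns ``estimate`` (per-year
    change in log relative abundance), ``se``, ``p``, ``q`` (BH FDR within
    this classifier's taxon set), and ``classifier``.
    """
    if "sample_id" in metadata.columns:
        metadata = metadata.set_index("sample_id")
    missing = [s for s in profile.samples if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing samples: {missing[:5]}")
    meta = metadata.loc[profile.samples]
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample IDs in metadata")

    logged, _ = log_transform(profile, pseudocount=pseudocount)
    rows = []
    for taxon in profile.taxa:
        fit = fit_taxon_model(
            logged.loc[taxon].to_numpy(), meta, covariates=covariates, cluster=cluster
        )
        rows.append(
            {
                "taxon": taxon,
                "estimate": fit.estimate,
                "se": fit.se,
                "p": fit.p_value,
                "classifier": profile.classifier_label,
            }
        )
    table = pd.DataFrame(rows).set_index("taxon")
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table
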