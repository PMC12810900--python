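"""Synthetic data generation and the combiner benchmark harness.

Two generators are provided:

* :func:`simulate_study_pair` draws paired per-feature association test
  results for two dependent studies (e.g. two classifiers profiling the
  same samples) from a Gaussian copula: latent statistics ``(Z1, Z2)`` are
  bivariate normal with a background correlation ``rho``; "conserved"
  features receive a positive mean shift in both studies, "unconserved"
  features in one randomly chosen study; the tail p-value is ``Phi(-Z)``,
  so the probit-transformed null p-values are exactly bivariate normal
  with correlation ``rho`` and the tetrachoric estimator is consistent for
  it.

* :func:`simulate_paired_profiles` builds an end-to-end fixture: a ground
  truth log-abundance matrix with planted per-taxon age slopes, viewed by
  two pseudo-classifiers that drop a controllable fraction of taxa and add
  multiplicative log-normal quantification noise.

:func:`run_benchmark` evaluates AdjMaxP against the Province-Borecki and
naive-concordance combiners over a scenario grid, reporting specificity,
sensitivity, precision and AUC for detecting conserved features at an FDR
threshold, and :func:`run_type1` measures nominal type-I error under the
global null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import adjmaxp as amp
from .diffabund import bh_fdr
from .profiles import TaxonProfile

__all__ = [
    "METHODS",
    "SimConfig",
    "SimStudy",
    "simulate_study_pair",
    "evaluate_nominal",
    "evaluate_fdr",
    "run_type1",
    "run_benchmark",
    "default_grid",
    "simulate_paired_profiles",
]

METHODS = ("adjmaxp", "province_borecki", "naive")


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for a two-study p-value simulation.

    ``background_correlation`` is the latent (probit-scale) correlation
    between the two studies' test statistics; signal strengths are mean
    shifts of the latent statistic in standard-normal units.
    """

    n_features: int = 400
    background_correlation: float = 0.0
    prop_conserved: float = 0.0
    prop_unconserved: float = 0.0
    signal_conserved: float = 3.0
    signal_unconserved: float = 3.0
    n_sims: int = 200

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not 0.0 <= self.background_correlation < 1.0:
            raise ValueError("background correlation must lie in [0, 1)")
        if self.prop_conserved < 0 or self.prop_unconserved < 0:
            raise ValueError("proportions must be non-negative")
        if self.prop_conserved + self.prop_unconserved > 1.0:
            raise ValueError("conserved + unconserved proportions exceed 1")
        if self.signal_conserved < 0 or self.signal_unconserved < 0:
            raise ValueError("signal shifts must be non-negative")
        if self.n_sims < 1:
            raise ValueError("n_sims must be positive")


@dataclass
class SimStudy:
    """One simulated replicate: p-values, effect signs, and truth labels."""

    p_values: np.ndarray  # (n_features, 2)
    signs: np.ndarray  # (n_features, 2), values in {-1, +1}
    labels: np.ndarray  # (n_features,), "null" | "conserved" | "unconserved"

    @property
    def n_features(self) -> int:
        return self.p_values.shape[0]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_study_pair(config: SimConfig, seed) -> SimStudy:
    """Draw one replicate of paired association results for two studies."""
    rng = _as_rng(seed)
    n = config.n_features
    rho = config.background_correlation
    n_cons = int(round(config.prop_conserved * n))
    n_uncons = int(round(config.prop_unconserved * n))

    labels = np.array(
        ["conserved"] * n_cons
        + ["unconserved"] * n_uncons
        + ["null"] * (n - n_cons - n_uncons)
    )
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    z[:n_cons, :] += config.signal_conserved
    which = rng.integers(0, 2, size=n_uncons)
    z[np.arange(n_cons, n_cons + n_uncons), which] += config.signal_unconserved

    p = stats.norm.sf(z)  # upper-tail p: added signal pushes p toward 0
    p = np.clip(p, amp.P_MIN, 1.0 - amp.P_MIN)
    signs = np.where(z >= 0, 1, -1)
    return SimStudy(p_values=p, signs=signs, labels=labels)


def _estimate_rt(pa: np.ndarray, pb: np.ndarray) -> float:
    try:
        return amp.tetrachoric_r(pa, pb)
    except ValueError:
        warnings.warn(
            "tetrachoric correlation unidentifiable in replicate; using 0",
            stacklevel=2,
        )
        return 0.0


def _method_calls_nominal(study: SimStudy, alpha: float) -> dict[str, np.ndarray]:
    pa, pb = study.p_values[:, 0], study.p_values[:, 1]
    r_t = _estimate_rt(pa, pb)
    k_eff = amp.effective_k(r_t, k=2)
    adj = amp.adjmaxp_combine(pa, pb, k_eff) <= alpha
    pb_p = amp.province_borecki_combine(pa, pb, r_t)
    naive = (
        (pa <= alpha) & (pb <= alpha) & (study.signs[:, 0] == study.signs[:, 1])
    )
    return {"adjmaxp": adj, "province_borecki": pb_p <= alpha, "naive": naive}


def evaluate_nominal(study: SimStudy, alpha: float = 0.05) -> dict[str, float]:
    """Per-method fraction of null features declared conserved at p <= alpha.

    The cross-study correlation is re-estimated from the replicate's own
    p-values, so estimation error is part of the evaluated procedure.
    """
    null_mask = study.labels == "null"
    if not null_mask.any():
        raise ValueError("no null features in study; cannot measure type-I error")
    calls = _method_calls_nominal(study, alpha)
    return {m: float(c[null_mask].mean()) for m, c in calls.items()}


def _scores_and_calls_fdr(
    study: SimStudy, q_threshold: float
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per method: (ranking score where larger = more conserved, FDR calls)."""
    pa, pb = study.p_values[:, 0], study.p_values[:, 1]
    r_t = _estimate_rt(pa, pb)
    k_eff = amp.effective_k(r_t, k=2)

    adj_p = amp.adjmaxp_combine(pa, pb, k_eff)
    pb_p = amp.province_borecki_combine(pa, pb, r_t)
    qa, qb = bh_fdr(pa), bh_fdr(pb)
    concordant = study.signs[:, 0] == study.signs[:, 1]
    naive_calls = (qa < q_threshold) & (qb < q_threshold) & concordant
    # naive ranking: smaller worst-case q is better; sign-discordant features
    # rank behind every concordant one
    naive_score = -np.maximum(qa, qb) - np.where(concordant, 0.0, 2.0)
    return {
        "adjmaxp": (-adj_p, bh_fdr(adj_p) < q_threshold),
        "province_borecki": (-pb_p, bh_fdr(pb_p) < q_threshold),
        "naive": (naive_score, naive_calls),
    }


def _rank_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    n1 = int(positives.sum())
    n0 = positives.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[positives].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate_fdr(study: SimStudy, q_threshold: float = 0.05) -> pd.DataFrame:
    """Confusion-matrix metrics for conserved-feature detection at FDR 0.05.

    Conserved features are the positive class; unconserved and null features
    both count as negatives (a method specific to conserved signal must not
    flag features shifted in only one study).  Precision is NaN when a
    method calls nothing.
    """
    truth = study.labels == "conserved"
    rows = []
    for method, (score, calls) in _scores_and_calls_fdr(study, q_threshold).items():
        tp = int((calls & truth).sum())
        fp = int((calls & ~truth).sum())
        fn = int((~calls & truth).sum())
        tn = int((~calls & ~truth).sum())
        rows.append(
            {
                "method": method,
                "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
                "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
                "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
                "auc": _rank_auc(score, truth),
            }
        )
    return pd.DataFrame(rows).set_index("method")


def run_type1(
    correlations: Sequence[float] = (0.2, 0.5, 0.8),
    n_features: int = 400,
    n_sims: int = 200,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean nominal type-I error per method under the global null.

    Returns a tidy table with one row per (correlation, method) holding the
    mean fraction of (null) features called conserved at ``p <= alpha`` and
    the binomial Monte-Carlo standard error of that mean.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for child, rho in zip(ss.spawn(len(correlations)), correlations):
        rng = np.random.default_rng(child)
        config = SimConfig(
            n_features=n_features, background_correlation=rho, n_sims=n_sims
        )
        rates: dict[str, list[float]] = {m: [] for m in METHODS}
        for _ in range(n_sims):
            study = simulate_study_pair(config, rng)
            for m, rate in evaluate_nominal(study, alpha).items():
                rates[m].append(rate)
        n_total = n_sims * n_features
        for m in METHODS:
            mean_rate = float(np.mean(rates[m]))
            rows.append(
                {
                    "background_correlation": rho,
                    "method": m,
                    "type1_error": mean_rate,
                    "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_total)),
                    "n_sims": n_sims,
                    "n_features": n_features,
                }
            )
    return pd.DataFrame(rows)


def default_grid(n_sims: int = 200, n_features: int = 400) -> list[SimConfig]:
    """Benchmark scenario grid: 20% conserved features, varying background
    correlation, unconserved-feature proportion, and signal strength."""
    grid = []
    for rho in (0.2, 0.5, 0.8):
        for prop_uncons in (0.0, 0.1, 0.25):
            for signal in (2.0, 3.0, 4.0):
                grid.append(
                    SimConfig(
                        n_features=n_features,
                        background_correlation=rho,
                        prop_conserved=0.2,
                        prop_unconserved=prop_uncons,
                        signal_conserved=signal,
                        signal_unconserved=signal,
                        n_sims=n_sims,
                    )
                )
    return grid


def run_benchmark(
    grid: Iterable[SimConfig] | None = None,
    seed: int | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Mean detection metrics per scenario and method over the grid.

    Deterministic under a fixed seed.  Precision and AUC are averaged over
    the replicates where they are defined; ``n_undefined_precision`` counts
    replicates in which a method called nothing.
    """
    grid = list(default_grid() if grid is None else grid)
    if not grid:
        raise ValueError("empty scenario grid")
    ss = np.random.SeedSequence(seed)
    rows = []
    for child, config in zip(ss.spawn(len(grid)), grid):
        rng = np.random.default_rng(child)
        per_method: dict[str, list[pd.Series]] = {m: [] for m in METHODS}
        for _ in range(config.n_sims):
            study = simulate_study_pair(config, rng)
            metrics = evaluate_fdr(study, q_threshold)
            for m in METHODS:
                per_method[m].append(metrics.loc[m])
        for m in METHODS:
            reps = pd.DataFrame(per_method[m])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                means = reps.mean(skipna=True)
            rows.append(
                {
                    "background_correlation": config.background_correlation,
                    "prop_conserved": config.prop_conserved,
                    "prop_unconserved": config.prop_unconserved,
                    "signal_conserved": config.signal_conserved,
                    "signal_unconserved": config.signal_unconserved,
                    "n_features": config.n_features,
                    "n_sims": config.n_sims,
                    "method": m,
                    "specificity": float(means["specificity"]),
                    "sensitivity": float(means["sensitivity"]),
                    "precision": float(means["precision"]),
                    "auc": float(means["auc"]),
                    "n_undefined_precision": int(reps["precision"].isna().sum()),
                }
            )
    return pd.DataFrame(rows)


def simulate_paired_profiles(
    n_samples: int = 300,
    n_taxa: int = 60,
    overlap_frac: float = 0.8,
    age_effects: Mapping[int, float] | None = None,
    classifier_noise: float = 0.3,
    seed: int | None = None,
) -> tuple[TaxonProfile, TaxonProfile, pd.DataFrame]:
    """Paired pseudo-classifier profiles with planted age effects.

    A ground-truth log-abundance matrix receives per-taxon age slopes
    (``age_effects`` maps taxon index to per-year log-abundance change).
    Each classifier view keeps a subset of taxa — ``overlap_frac`` of taxa
    are seen by both, the remainder split between the views — applies
    multiplicative log-normal quantification noise, and renormalizes.
    Metadata mimics a family-structured ageing cohort: ages 55-105, binary
    sex, three education levels, and two-person family clusters for about
    half the participants.
    """
    if not 0.0 <= overlap_frac <= 1.0:
        raise ValueError("overlap_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]
    taxa = [f"taxon_{i:03d}" for i in range(n_taxa)]

    ages = rng.uniform(55.0, 105.0, size=n_samples)
    sex = rng.choice(["female", "male"], size=n_samples)
    education = rng.choice(["primary", "secondary", "tertiary"], size=n_samples)
    family = np.arange(n_samples).astype(object)
    # pair up roughly half the samples into two-person families
    n_pairs = n_samples // 4
    pair_members = rng.permutation(n_samples)[: 2 * n_pairs]
    for j in range(n_pairs):
        a_idx, b_idx = pair_members[2 * j], pair_members[2 * j + 1]
        family[b_idx] = family[a_idx]
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "age": ages,
            "sex": sex,
            "education": education,
            "family_id": [f"F{int(f):04d}" for f in family],
        }
    )

    slopes = np.zeros(n_taxa)
    if age_effects:
        for idx, slope in age_effects.items():
            slopes[int(idx)] = slope

    baseline = rng.normal(0.0, 1.5, size=n_taxa)
    centered_age = ages - ages.mean()
    log_true = (
        baseline[:, None]
        + slopes[:, None] * centered_age[None, :]
        + rng.normal(0.0, 0.5, size=(n_taxa, n_samples))
    )

    n_both = int(round(overlap_frac * n_taxa))
    order = rng.permutation(n_taxa)
    both = order[:n_both]
    rest = order[n_both:]
    only_a = rest[::2]
    only_b = rest[1::2]
    keep_a = np.sort(np.concatenate([both, only_a])).astype(int)
    keep_b = np.sort(np.concatenate([both, only_b])).astype(int)

    def view(keep: np.ndarray, label: str) -> TaxonProfile:
        noise = rng.normal(0.0, classifier_noise, size=(keep.size, n_samples))
        raw = np.exp(log_true[keep, :] + noise)
        rel = raw / raw.sum(axis=0, keepdims=True)
        data = pd.DataFrame(rel, index=[taxa[i] for i in keep], columns=samples)
        return TaxonProfile(classifier_label=label, level="species", data=data)

    return view(keep_a, "sim_a"), view(keep_b, "sim_b"), metadata
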