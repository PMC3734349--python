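"""Bayesian model comparison: log Bayes factors, evidence categories,
and random-effects Bayesian model selection (RFX BMS).

The feedback statistic is logBF = F(M_aL) - F(M_aR) in nats; positive
values indicate dominance of the attention-left model.  Group-level
dominance is summarized by exceedance probabilities from a variational
Dirichlet model over per-subject model frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma
from scipy.stats import beta as beta_dist

__all__ = [
    "ComparisonResult",
    "RFXResult",
    "log_bayes_factor",
    "classify_evidence",
    "rfx_bms",
]

#: Bayes-factor thresholds of the standard evidence categories
WEAK_MAX = 3.0
POSITIVE_MAX = 20.0


@dataclass(frozen=True)
class ComparisonResult:
    logBF: float
    dominant_model: str | None
    evidence_category: str  # "weak" | "positive" | "strong+"


def classify_evidence(bayes_factor: float) -> str:
    """Map a Bayes factor (natural scale, >= 1 side) to its category.

    < 3: weak; 3-20: positive; > 20: strong (and very strong) evidence.
    """
    if bayes_factor < 0:
        raise ValueError(
            "Bayes factor must be non-negative; exponentiate |logBF| first"
        )
    if bayes_factor < WEAK_MAX:
        return "weak"
    if bayes_factor <= POSITIVE_MAX:
        return "positive"
    return "strong+"


def log_bayes_factor(
    F1: float, F2: float, names: tuple[str, str] = ("M_aL", "M_aR")
) -> ComparisonResult:
    """logBF = F1 - F2; positive means the first model dominates."""
    if not (np.isfinite(F1) and np.isfinite(F2)):
        raise ValueError("free energies must be finite")
    logbf = float(F1 - F2)
    if logbf > 0:
        dominant = names[0]
    elif logbf < 0:
        dominant = names[1]
    else:
        dominant = None
    return ComparisonResult(
        logBF=logbf,
        dominant_model=dominant,
        evidence_category=classify_evidence(float(np.exp(abs(logbf)))),
    )


@dataclass(frozen=True)
class RFXResult:
    alpha: np.ndarray       # Dirichlet concentration per model
    expected_r: np.ndarray  # expected model frequencies
    Pe: np.ndarray          # exceedance probability per model


def rfx_bms(
    log_evidences: np.ndarray,
    prior_alpha: float = 1.0,
    n_samples: int = 100_000,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> RFXResult:
    """Random-effects Bayesian model selection over subjects x models.

    Fits a Dirichlet distribution over population model frequencies by
    the variational scheme (soft-assigning each subject to models by
    its log evidences), then computes each model's exceedance
    probability — the probability that its frequency is the largest.
    The two-model case is exact via the Beta distribution
    (P(r1 > 0.5)); more models use seeded Dirichlet Monte-Carlo.
    """
    L = np.atleast_2d(np.asarray(log_evidences, dtype=float))
    n_subj, n_models = L.shape
    if n_models < 2:
        raise ValueError("rfx_bms needs at least two models")
    if n_subj < 1:
        raise ValueError("rfx_bms needs at least one subject")

    alpha0 = np.full(n_models, float(prior_alpha))
    alpha = alpha0.copy()
    for _ in range(max_iter):
        logu = L + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    expected_r = alpha / alpha.sum()
    if n_models == 2:
        pe1 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        Pe = np.array([pe1, 1.0 - pe1])
    else:
        rng = np.random.default_rng(seed)
        draws = rng.dirichlet(alpha, size=n_samples)
        winners = np.argmax(draws, axis=1)
        Pe = np.bincount(winners, minlength=n_models) / n_samples
    return RFXResult(alpha=alpha, expected_r=expected_r, Pe=Pe)
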