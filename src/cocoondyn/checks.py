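"""Deviance-based posterior predictive checks.

For each retained draw the observation-layer expectations (the Poisson means
for the chosen count category) are reconstructed from that draw's full latent
state, a replicated dataset is simulated from those means, and the deviance
of the observed and replicated counts is compared.  The Bayesian P-value is
the fraction of draws whose replicated deviance is at least the observed one
(ties count); values outside (0.05, 0.95) flag a model-data discrepancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CocoonCounts, ValidationError, poisson_logpmf, expected_counts_grid
from .mcmc import PosteriorSamples

CATEGORIES = ("I", "M", "H")


@dataclass
class PpcResult:
    category: str
    bayesian_p: float
    n_draws: int
    observed_deviance: np.ndarray     # (n_draws,)
    replicated_deviance: np.ndarray   # (n_draws,)


def deviance(counts, lambdas, mask=None) -> float:
    """-2 times the Poisson log-likelihood of ``counts`` at means ``lambdas``.

    Returns +inf when a zero mean meets a positive count.
    """
    counts = np.asarray(counts, dtype=float)
    lam = np.asarray(lambdas, dtype=float)
    if counts.shape != lam.shape:
        raise ValidationError("counts and lambdas must have matching shapes")
    if not np.all(np.isfinite(lam)):
        raise ValidationError("non-finite expected counts")
    terms = poisson_logpmf(counts, lam)
    if mask is not None:
        terms = np.where(mask, terms, 0.0)
    total = terms.sum()
    return float(np.inf) if np.isneginf(total) else float(-2.0 * total)


def _lambda_draws(samples: PosteriorSamples) -> tuple[np.ndarray, ...]:
    """Per-draw Poisson means, each (chains, draws, S, J, T)."""
    return expected_counts_grid(
        samples.get("phi"),
        samples.get("N"), samples.get("theta"), samples.get("kappa"),
        samples.get("kappa0"), samples.get("poolI"), samples.get("poolM"),
        samples.get("poolH"), samples.first_year, samples.options)


def posterior_predictive_pvalue(counts: CocoonCounts,
                                samples: PosteriorSamples,
                                category: str,
                                rng: np.random.Generator | None = None,
                                min_draws: int = 100,
                                _lambdas=None) -> PpcResult:
    """Deviance-based Bayesian P-value for one count category.

    The replication is of the observation layer only: each retained draw's
    expectations are held fixed and fresh Poisson counts are drawn at them.
    """
    if category not in CATEGORIES:
        raise ValidationError(f"category must be one of {CATEGORIES}")
    if rng is None:
        rng = np.random.default_rng()
    n_draws = samples.n_chains * samples.n_draws
    if n_draws < min_draws:
        raise ValidationError(
            f"need at least {min_draws} retained draws, have {n_draws}")
    if _lambdas is None:
        _lambdas = _lambda_draws(samples)
    lam = _lambdas[CATEGORIES.index(category)]
    y = getattr(counts, category).astype(float)
    m = counts.mask
    # per-draw observed deviance
    terms = poisson_logpmf(y, lam) * m
    d_obs = -2.0 * terms.sum(axis=(2, 3, 4)).ravel()
    # replicated counts at the same means
    y_rep = rng.poisson(lam)
    terms_rep = poisson_logpmf(y_rep, lam) * m
    d_rep = -2.0 * terms_rep.sum(axis=(2, 3, 4)).ravel()
    p = float(np.mean(d_rep >= d_obs))
    return PpcResult(category=category, bayesian_p=p, n_draws=n_draws,
                     observed_deviance=d_obs, replicated_deviance=d_rep)


def ppc_all_categories(counts, samples, rng=None) -> list[PpcResult]:
    """Per-category checks plus nothing else; the joint deviance over all
    three categories is available via :func:`joint_ppc_pvalue`."""
    if rng is None:
        rng = np.random.default_rng()
    lams = _lambda_draws(samples)        # shared across the three categories
    return [posterior_predictive_pvalue(counts, samples, c, rng,
                                        _lambdas=lams)
            for c in CATEGORIES]


def joint_ppc_pvalue(counts, samples, rng=None) -> float:
    """Supplementary joint Bayesian P-value over all three categories."""
    if rng is None:
        rng = np.random.default_rng()
    lams = _lambda_draws(samples)
    m = counts.mask
    d_obs = 0.0
    d_rep = 0.0
    for c, lam in zip(CATEGORIES, lams):
        y = getattr(counts, c).astype(float)
        d_obs = d_obs - 2.0 * (poisson_logpmf(y, lam) * m).sum(axis=(2, 3, 4))
        y_rep = rng.poisson(lam)
        d_rep = d_rep - 2.0 * (poisson_logpmf(y_rep, lam) * m).sum(axis=(2, 3, 4))
    return float(np.mean(d_rep.ravel() >= d_obs.ravel()))
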