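"""Process model, likelihood and priors for multi-year cocoon count data.

The model describes what an annual mid-October soil sample contains. Each
0.04-m^2 sample ``j`` at site ``i`` in year ``t`` yields three counts:

* ``I`` — unopened cocoons, i.e. the current generation's cocoons that were
  not preyed on by small mammals between spinning and sampling;
* ``M`` — cocoon shells opened by small-mammal predation, which accumulate
  across generations because empty shells persist in the soil;
* ``H`` — shells emptied by anything else (adult or parasitoid emergence,
  disease), which by definition belong to previous generations only.

Counts are Poisson observations of per-sample expectations built from a
latent cohort recursion: ``N`` newly spun cocoons suffer predation at rate
``theta`` before sampling; cocoons still intact at sampling are preyed on at
rate ``kappa`` before the next summer's emergence; and empty shells survive
from one October to the next with annual remaining rate ``phi``.  Because
the previous year's leftovers inside this year's sample cannot be observed,
they enter as latent pools (``Iprev``, ``Mprev``, ``Hprev``) with
moment-matched gamma priors built from the previous year's observed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


# --------------------------------------------------------------------------
# observed data container
# --------------------------------------------------------------------------

_COUNT_COLUMNS = ["site", "sample", "year", "I", "M", "H"]


@dataclass
class CocoonCounts:
    """Observed (site, sample, year) cocoon counts on a dense grid.

    Data are stored as ``(n_sites, n_samples, n_years)`` integer arrays plus a
    boolean ``mask`` marking which cells were actually observed, so ragged
    designs (sites with fewer samples, or shorter year runs) are representable.
    Years are global and contiguous; per-site year runs must be contiguous.
    """

    sites: np.ndarray          # (S,) site identifiers
    samples: np.ndarray        # (J,) sample identifiers
    years: np.ndarray          # (T,) contiguous integer years
    I: np.ndarray              # (S, J, T) int
    M: np.ndarray              # (S, J, T) int
    H: np.ndarray              # (S, J, T) int
    mask: np.ndarray           # (S, J, T) bool

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_sites, self.n_samples, self.n_years)

    def site_index(self, site) -> int:
        idx = np.nonzero(self.sites == site)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown site {site!r}")
        return int(idx[0])

    def year_index(self, year) -> int:
        idx = np.nonzero(self.years == year)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown year {year!r}")
        return int(idx[0])

    def sample_index(self, sample) -> int:
        idx = np.nonzero(self.samples == sample)[0]
        if len(idx) == 0:
            raise KeyError(f"unknown sample {sample!r}")
        return int(idx[0])

    def first_year_mask(self) -> np.ndarray:
        """(S, T) boolean: is year t the first observed year at site i?"""
        present = self.mask.any(axis=1)            # (S, T)
        first = np.zeros_like(present)
        for i in range(present.shape[0]):
            obs = np.nonzero(present[i])[0]
            if len(obs):
                first[i, obs[0]] = True
        return first

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CocoonCounts":
        missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"count table is missing columns {missing}")
        df = df[_COUNT_COLUMNS].copy()
        for col in ["I", "M", "H"]:
            vals = df[col].to_numpy()
            if not np.all(np.isfinite(vals)):
                raise ValidationError(f"column {col} contains non-finite values")
            if np.any(vals != np.floor(vals)):
                bad = df.index[vals != np.floor(vals)][0]
                raise ValidationError(f"column {col} must be integer (row {bad})")
            if np.any(vals < 0):
                bad = df.index[vals < 0][0]
                raise ValidationError(f"column {col} is negative in row {bad}")
        if df.duplicated(subset=["site", "sample", "year"]).any():
            dup = df[df.duplicated(subset=["site", "sample", "year"])].iloc[0]
            raise ValidationError(
                f"duplicate (site, sample, year) key: "
                f"({dup['site']}, {dup['sample']}, {dup['year']})")
        years_all = np.sort(df["year"].unique().astype(int))
        if len(years_all) > 1 and np.any(np.diff(years_all) != 1):
            raise ValidationError(
                f"observed years {years_all.tolist()} are not contiguous")
        for site, grp in df.groupby("site"):
            ys = np.sort(grp["year"].unique().astype(int))
            if len(ys) > 1 and np.any(np.diff(ys) != 1):
                raise ValidationError(
                    f"site {site!r} has a gap in its year run {ys.tolist()}; "
                    "the carryover recursion needs consecutive years")
        sites = np.array(sorted(df["site"].unique().tolist()))
        samples = np.array(sorted(df["sample"].unique().tolist()))
        S, J, T = len(sites), len(samples), len(years_all)
        I = np.zeros((S, J, T), dtype=np.int64)
        M = np.zeros((S, J, T), dtype=np.int64)
        H = np.zeros((S, J, T), dtype=np.int64)
        mask = np.zeros((S, J, T), dtype=bool)
        si = {s: k for k, s in enumerate(sites.tolist())}
        ji = {s: k for k, s in enumerate(samples.tolist())}
        ti = {int(y): k for k, y in enumerate(years_all.tolist())}
        for row in df.itertuples(index=False):
            a, b, c = si[row.site], ji[row.sample], ti[int(row.year)]
            I[a, b, c] = int(row.I)
            M[a, b, c] = int(row.M)
            H[a, b, c] = int(row.H)
            mask[a, b, c] = True
        return cls(sites=sites, samples=samples, years=years_all,
                   I=I, M=M, H=H, mask=mask)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for a, site in enumerate(self.sites):
            for b, sample in enumerate(self.samples):
                for c, year in enumerate(self.years):
                    if self.mask[a, b, c]:
                        recs.append((site, sample, int(year),
                                     int(self.I[a, b, c]),
                                     int(self.M[a, b, c]),
                                     int(self.H[a, b, c])))
        return pd.DataFrame(recs, columns=_COUNT_COLUMNS)


# --------------------------------------------------------------------------
# expectations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpectedCounts:
    """Per-sample Poisson means for the three observed categories."""

    lambda_I: float
    lambda_M: float
    lambda_H: float


@dataclass(frozen=True)
class ProcessOptions:
    """Switches for the gaps the verbal model description leaves open.

    phi_on_fresh_empties
        If True (default) the annual shell-survival rate ``phi`` multiplies
        every carried-over term, including shells emptied during the year
        just before sampling; if False those freshly emptied shells enter
        without decay and only the older pools decay.
    zero_history
        If True each site's first observed year carries no latent history
        (pools fixed at zero) and a small floor keeps the Poisson means of
        the empty categories positive; if False (default) the first year
        gets free latent pools with vague gamma priors.
    """

    phi_on_fresh_empties: bool = True
    zero_history: bool = False
    lambda_floor: float = 1e-6


def expected_counts_grid(phi, N, theta, kappa, kappa0, poolI, poolM, poolH,
                         first_year, options: ProcessOptions | None = None):
    """Vectorized cohort recursion over dense ``(..., S, J, T)`` arrays.

    ``phi`` broadcasts against the leading axes (scalar, or one value per
    chain); ``kappa0`` is the dummy previous-year predation rate used at each
    site's first observed year and has shape ``(..., S, J)``; ``first_year``
    is the (S, T) boolean from :meth:`CocoonCounts.first_year_mask`.

    Returns ``(lambda_I, lambda_M, lambda_H)`` with the same shape as ``N``.
    """
    if options is None:
        options = ProcessOptions()
    phi = np.asarray(phi)
    if phi.ndim:                                    # per-chain phi
        phi = phi[(...,) + (None,) * 3]
    shifted = np.concatenate([kappa0[..., None], kappa[..., :-1]], axis=-1)
    kprev = np.where(first_year[..., :, None, :], kappa0[..., None], shifted)
    if options.zero_history:
        zero = first_year[..., :, None, :]
        poolI = np.where(zero, 0.0, poolI)
        poolM = np.where(zero, 0.0, poolM)
        poolH = np.where(zero, 0.0, poolH)
    lam_I = N * (1.0 - theta)
    if options.phi_on_fresh_empties:
        lam_M = N * theta + phi * (kprev * poolI + poolM)
        lam_H = phi * ((1.0 - kprev) * poolI + poolH)
    else:
        lam_M = N * theta + kprev * poolI + phi * poolM
        lam_H = (1.0 - kprev) * poolI + phi * poolH
    if options.zero_history:
        lam_M = np.maximum(lam_M, options.lambda_floor)
        lam_H = np.maximum(lam_H, options.lambda_floor)
    return lam_I, lam_M, lam_H


# --------------------------------------------------------------------------
# model state
# --------------------------------------------------------------------------

@dataclass
class ModelState:
    """One complete set of parameters and latent variables.

    Site-year arrays are ``(S, T)``; per-sample arrays are ``(S, J, T)``.
    ``Iprev/Mprev/Hprev`` are indexed by the year they feed into: entry
    ``[..., t]`` is the latent leftover pool present in year ``t``'s sample.
    ``kappa0`` is the dummy predation rate applied to each site's first-year
    history pool.  ``kappa`` for the final observed year has no following
    year to constrain it; ``final_year_kappa_unconstrained`` records that.
    """

    phi: float
    p_theta: np.ndarray
    p_kappa: np.ndarray
    k_theta: float
    k_kappa: float
    N_mean: np.ndarray
    s: float
    N: np.ndarray
    theta: np.ndarray
    kappa: np.ndarray
    Iprev: np.ndarray
    Mprev: np.ndarray
    Hprev: np.ndarray
    kappa0: np.ndarray
    sites: np.ndarray
    years: np.ndarray
    first_year: np.ndarray                 # (S, T) bool
    final_year_kappa_unconstrained: bool = True

    @property
    def shape(self):
        return self.N.shape

    def validate(self) -> None:
        S, J, T = self.shape
        def _chk(name, arr, shape):
            arr = np.asarray(arr)
            if arr.shape != shape:
                raise ValidationError(f"{name} has shape {arr.shape}, expected {shape}")
        _chk("p_theta", self.p_theta, (S, T))
        _chk("p_kappa", self.p_kappa, (S, T))
        _chk("N_mean", self.N_mean, (S, T))
        for name in ("theta", "kappa", "N", "Iprev", "Mprev", "Hprev"):
            _chk(name, getattr(self, name), (S, J, T))
        _chk("kappa0", self.kappa0, (S, J))
        if not (0.0 <= self.phi <= 1.0):
            raise ValidationError(f"phi={self.phi} outside [0, 1]")
        for name in ("p_theta", "p_kappa", "theta", "kappa", "kappa0"):
            arr = np.asarray(getattr(self, name))
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError(f"{name} has entries outside [0, 1]")
        for name in ("k_theta", "k_kappa", "s"):
            if not np.asarray(getattr(self, name)) > 0:
                raise ValidationError(f"{name} must be > 0")
        if np.any(self.N_mean <= 0) or np.any(self.N <= 0):
            raise ValidationError("N and N_mean must be > 0")
        for name in ("Iprev", "Mprev", "Hprev"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"{name} must be >= 0")


def expected_counts(state: ModelState, site, sample, year,
                    counts: CocoonCounts | None = None,
                    options: ProcessOptions | None = None) -> ExpectedCounts:
    """Expected ``(lambda_I, lambda_M, lambda_H)`` for one keyed sample cell."""
    if counts is not None:
        i, j, t = (counts.site_index(site), counts.sample_index(sample),
                   counts.year_index(year))
    else:
        i = int(np.nonzero(state.sites == site)[0][0]) if site in state.sites else None
        if i is None:
            raise KeyError(f"unknown site {site!r}")
        t_arr = np.nonzero(state.years == year)[0]
        if len(t_arr) == 0:
            raise KeyError(f"unknown year {year!r}")
        t = int(t_arr[0])
        j = int(sample) - 1
        if not (0 <= j < state.shape[1]):
            raise KeyError(f"sample {sample!r} outside 1..{state.shape[1]}")
    for name in ("Iprev", "Mprev", "Hprev"):
        if getattr(state, name)[i, j, t] < 0:
            raise ValidationError(f"negative latent pool {name}[{site},{sample},{year}]")
    lam_I, lam_M, lam_H = expected_counts_grid(
        state.phi, state.N, state.theta, state.kappa, state.kappa0,
        state.Iprev, state.Mprev, state.Hprev, state.first_year, options)
    return ExpectedCounts(float(lam_I[i, j, t]), float(lam_M[i, j, t]),
                          float(lam_H[i, j, t]))


# --------------------------------------------------------------------------
# densities
# --------------------------------------------------------------------------

def poisson_logpmf(y, lam):
    """Elementwise Poisson log-probability; -inf where lam=0 and y>0."""
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = xlogy(y, lam) - lam - gammaln(y + 1.0)
    return out


def gamma_logpdf(x, shape, rate):
    with np.errstate(divide="ignore", invalid="ignore"):
        return (shape * np.log(rate) - gammaln(shape)
                + xlogy(shape - 1.0, x) - rate * x)


def invgamma_logpdf(x, shape, scale):
    with np.errstate(divide="ignore"):
        return (shape * np.log(scale) - gammaln(shape)
                - (shape + 1.0) * np.log(x) - scale / x)


def beta_logpdf(x, a, b):
    with np.errstate(divide="ignore", invalid="ignore"):
        return (gammaln(a + b) - gammaln(a) - gammaln(b)
                + xlogy(a - 1.0, x) + xlogy(b - 1.0, 1.0 - x))


def log_likelihood(counts: CocoonCounts, state: ModelState,
                   options: ProcessOptions | None = None) -> float:
    """Poisson log-likelihood of all observed cells under ``state``."""
    lam_I, lam_M, lam_H = expected_counts_grid(
        state.phi, state.N, state.theta, state.kappa, state.kappa0,
        state.Iprev, state.Mprev, state.Hprev, state.first_year, options)
    if not (np.all(np.isfinite(lam_I)) and np.all(np.isfinite(lam_M))
            and np.all(np.isfinite(lam_H))):
        raise ValidationError("non-finite expected counts")
    m = counts.mask
    total = (poisson_logpmf(counts.I, lam_I)[m].sum()
             + poisson_logpmf(counts.M, lam_M)[m].sum()
             + poisson_logpmf(counts.H, lam_H)[m].sum())
    return float(total)


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------

def moment_matched_gamma(observations: Sequence[float],
                         variance_floor: float = 0.25,
                         mean_floor: float = 0.1) -> tuple[float, float]:
    """Gamma (shape, rate) with the sample's mean and variance.

    Sparse cells need guarding: an all-equal sample has zero variance and an
    all-zero sample has zero mean, either of which would make the matched
    gamma degenerate, so both moments are floored first.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise ValidationError("moment matching needs at least one observation")
    mean = max(float(obs.mean()), mean_floor)
    var = max(float(obs.var(ddof=0)), variance_floor)
    return mean * mean / var, mean / var


_GAMMA_11 = ("gamma", 1.0, 1.0)
_INVGAMMA_VAGUE = ("invgamma", 0.001, 0.001)


@dataclass
class PriorSpec:
    """Prior families and hyperparameters, plus the moment-matched pools.

    ``pool_shape``/``pool_rate`` are ``(S, T, 3)`` arrays (categories ordered
    I, M, H) giving the gamma prior of the latent pool feeding year ``t``;
    for each site's first observed year they hold the vague initial-history
    prior instead of a moment match.
    """

    pool_shape: np.ndarray
    pool_rate: np.ndarray
    first_year: np.ndarray                      # (S, T) bool
    k_prior: tuple = _GAMMA_11
    s_prior: tuple = _INVGAMMA_VAGUE
    n_mean_prior: tuple = _INVGAMMA_VAGUE
    init_pool_prior: tuple = ("gamma", 0.001, 0.001)
    options: ProcessOptions = field(default_factory=ProcessOptions)

    @classmethod
    def from_counts(cls, counts: CocoonCounts,
                    variance_floor: float = 0.25,
                    mean_floor: float = 0.1,
                    **kwargs) -> "PriorSpec":
        """Build pool priors by matching each site-year's previous-year counts."""
        S, J, T = counts.shape
        first = counts.first_year_mask()
        init = kwargs.get("init_pool_prior", cls.init_pool_prior)
        shape = np.full((S, T, 3), init[1], dtype=float)
        rate = np.full((S, T, 3), init[2], dtype=float)
        cats = (counts.I, counts.M, counts.H)
        for i in range(S):
            for t in range(T):
                if first[i, t] or not counts.mask[i, :, t].any():
                    continue
                prev = counts.mask[i, :, t - 1]
                if not prev.any():
                    continue
                for c, arr in enumerate(cats):
                    a, b = moment_matched_gamma(arr[i, prev, t - 1],
                                                variance_floor, mean_floor)
                    shape[i, t, c] = a
                    rate[i, t, c] = b
        return cls(pool_shape=shape, pool_rate=rate, first_year=first, **kwargs)


def positive_logpdf(x, prior: tuple):
    """Log-density of a ('gamma', shape, rate) or ('invgamma', shape, scale)."""
    family, a, b = prior
    if family == "gamma":
        return gamma_logpdf(x, a, b)
    if family == "invgamma":
        return invgamma_logpdf(x, a, b)
    raise ValidationError(f"unknown prior family {family!r}")


def log_prior(state: ModelState, priors: PriorSpec) -> float:
    """Joint log prior density of every parameter and latent variable.

    Returns -inf (never raises) for states outside the support.
    """
    if not (0.0 <= state.phi <= 1.0):
        return -np.inf
    for arr in (state.p_theta, state.p_kappa, state.kappa0):
        if np.any(arr < 0) or np.any(arr > 1):
            return -np.inf
    for arr in (state.theta, state.kappa):
        if np.any(arr <= 0) or np.any(arr >= 1):
            return -np.inf
    if state.k_theta <= 0 or state.k_kappa <= 0 or state.s <= 0:
        return -np.inf
    if np.any(state.N_mean <= 0) or np.any(state.N <= 0):
        return -np.inf
    for name in ("Iprev", "Mprev", "Hprev"):
        if np.any(getattr(state, name) < 0):
            return -np.inf

    total = 0.0  # uniform terms for phi, p_theta, p_kappa, kappa0 contribute 0
    total += positive_logpdf(state.k_theta, priors.k_prior)
    total += positive_logpdf(state.k_kappa, priors.k_prior)
    total += positive_logpdf(state.s, priors.s_prior)
    total += positive_logpdf(state.N_mean, priors.n_mean_prior).sum()

    a_th = state.k_theta * state.p_theta[:, None, :]
    b_th = state.k_theta * (1.0 - state.p_theta[:, None, :])
    total += beta_logpdf(state.theta, a_th, b_th).sum()
    a_ka = state.k_kappa * state.p_kappa[:, None, :]
    b_ka = state.k_kappa * (1.0 - state.p_kappa[:, None, :])
    total += beta_logpdf(state.kappa, a_ka, b_ka).sum()

    shape_N = state.N_mean[:, None, :] / state.s
    total += gamma_logpdf(state.N, shape_N, 1.0 / state.s).sum()

    pools = (state.Iprev, state.Mprev, state.Hprev)
    for c, pool in enumerate(pools):
        a = priors.pool_shape[:, None, :, c]
        b = priors.pool_rate[:, None, :, c]
        term = gamma_logpdf(pool, a, b)
        if priors.options.zero_history:
            # first-year pools are fixed at zero, not latent
            term = np.where(priors.first_year[:, None, :], 0.0, term)
        total += term.sum()
    if not np.isfinite(total):
        return -np.inf
    return float(total)


# --------------------------------------------------------------------------
# derived quantities
# --------------------------------------------------------------------------

def total_predation_rate(theta, kappa):
    """Predation probability over the whole cocoon period.

    A cocoon escapes predation only by surviving both intervals, so
    ``rho = 1 - (1 - theta) * (1 - kappa)``; the identity
    ``rho = theta + (1 - theta) * kappa`` is equivalent.
    """
    theta = np.asarray(theta, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1) or np.any(kappa < 0) or np.any(kappa > 1):
        raise ValidationError("predation rates must lie in [0, 1]")
    rho = 1.0 - (1.0 - theta) * (1.0 - kappa)
    if rho.ndim == 0:
        return float(rho)
    return rho
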