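"""Random-walk Metropolis-Hastings sampler for the cocoon dynamics model.

The posterior has a few thousand dimensions (per-sample latent cocoon
numbers, predation rates and shell pools, plus site-year means and four
global hyperparameters), so the sampler works block-wise on a chain-stacked
state: every array carries a leading chain axis and all chains advance in
lock-step from a single seeded generator.  Proposals are symmetric Gaussian
steps in transformed space (logit for rates, log for positive quantities)
with the change of variables absorbed into the acceptance ratio.

Blocking exploits the model's conditional independence.  The per-sample
triple (N, theta, kappa) at year t influences the likelihood at year t (via
N, theta) and at year t+1 (via kappa), so cell triples are updated on a
checkerboard over years: all even-year cells in one vectorized batch, then
all odd-year cells.  Latent shell pools touch only their own year and are
updated in a single batch (jointly with the dummy first-year predation rate
where applicable); site-year means and hyperparameters follow.  Step sizes
are tuned by Robbins-Monro adaptation during burn-in only and frozen
afterwards, so the post-burn-in kernel is a fixed, valid MH kernel.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit, xlogy

from .model import (CocoonCounts, ModelState, PriorSpec, ProcessOptions,
                    ValidationError, expected_counts_grid, positive_logpdf)

__all__ = [
    "ChainConfig", "PosteriorSamples", "CocoonSampler", "run_chains",
    "mh_step", "random_walk_mh", "gelman_rubin", "hpd_interval",
]


# --------------------------------------------------------------------------
# generic random-walk Metropolis-Hastings
# --------------------------------------------------------------------------

def mh_step(log_density, x, step, rng, current_logp=None):
    """One symmetric Gaussian random-walk MH step.

    Returns ``(new_x, accepted, new_logp)``.  With ``step=0`` the proposal
    equals the current point and is always accepted.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if current_logp is None:
        current_logp = float(log_density(x))
    if not np.isfinite(current_logp):
        raise ValidationError("log density is non-finite at the current state")
    prop = x + step * rng.standard_normal(x.shape)
    lp = float(log_density(prop))
    if math.log(rng.random()) < lp - current_logp:
        return prop, True, lp
    return x, False, current_logp


def random_walk_mh(log_density, x0, step, n_steps, rng,
                   burn_in=0, thin=1):
    """Run a plain random-walk MH chain; returns (samples, acceptance_rate)."""
    x = np.atleast_1d(np.asarray(x0, dtype=float))
    lp = float(log_density(x))
    keep = []
    n_acc = 0
    for it in range(1, n_steps + 1):
        x, acc, lp = mh_step(log_density, x, step, rng, current_logp=lp)
        n_acc += acc
        if it > burn_in and (it - burn_in) % thin == 0:
            keep.append(x.copy())
    return np.asarray(keep), n_acc / n_steps


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def gelman_rubin(traces) -> float:
    """Potential scale reduction factor over m chains of length n.

    Uses the classical m-chain estimator: with W the mean within-chain
    variance (ddof=1) and B/n the between-chain variance of the chain means
    (with the n/(m-1) factor), returns ``sqrt(((n-1)/n * W + B/n) / W)``.
    Returns NaN with a warning when the pooled within-chain variance is zero.
    """
    x = np.asarray(traces, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need >= 2 chains with >= 2 draws each")
    m, n = x.shape
    W = x.var(axis=1, ddof=1).mean()
    B = n * x.mean(axis=1).var(ddof=1)
    if W == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined")
        return float("nan")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def hpd_interval(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws (Chen-Shao).

    Sorts the draws and slides a window of ``ceil(mass * n)`` order
    statistics, returning the narrowest; ties go to the lowest window.
    """
    if not 0.0 < mass < 1.0:
        raise ValidationError("mass must lie strictly inside (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < math.ceil(1.0 / (1.0 - mass)):
        raise ValidationError(f"need at least {math.ceil(1/(1-mass))} samples")
    k = math.ceil(mass * n)
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))           # argmin takes the first minimum
    return float(x[i]), float(x[i + k - 1])


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class ChainConfig:
    """MCMC run settings.  Defaults are the full-scale study settings
    (3 chains x 5e5 iterations, 2e5 burn-in, thin 100); :meth:`desk` gives a
    ten-times-smaller preset for interactive work and test suites."""

    n_chains: int = 3
    n_iterations: int = 500_000
    burn_in: int = 200_000
    thin: int = 100
    seed: int = 0
    adapt: bool = True
    target_scalar: float = 0.44
    target_block: float = 0.23
    step_scales: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_chains < 1 or self.n_iterations < 1 or self.thin < 1:
            raise ValidationError("chain dimensions must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValidationError("need 0 <= burn_in < n_iterations")
        if self.thin > self.n_iterations - self.burn_in:
            raise ValidationError("thin exceeds the post-burn-in run length")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @classmethod
    def desk(cls, seed: int = 0, **kwargs) -> "ChainConfig":
        kwargs.setdefault("n_iterations", 50_000)
        kwargs.setdefault("burn_in", 20_000)
        kwargs.setdefault("thin", 10)
        return cls(seed=seed, **kwargs)

    @classmethod
    def paper_scale(cls, seed: int = 0, **kwargs) -> "ChainConfig":
        return cls(seed=seed, **kwargs)


# --------------------------------------------------------------------------
# parameter layout / posterior container
# --------------------------------------------------------------------------

_BLOCK_SHAPES = {
    "phi": (), "s": (), "k_theta": (), "k_kappa": (),
    "p_theta": "ST", "p_kappa": "ST", "N_mean": "ST",
    "N": "SJT", "theta": "SJT", "kappa": "SJT", "kappa0": "SJ",
    "poolI": "SJT", "poolM": "SJT", "poolH": "SJT",
}


class ParamLayout:
    """Fixed flattening order of the model state into one vector."""

    def __init__(self, S: int, J: int, T: int):
        self.S, self.J, self.T = S, J, T
        dims = {"ST": (S, T), "SJT": (S, J, T), "SJ": (S, J)}
        self.shapes = {k: (dims[v] if isinstance(v, str) else v)
                       for k, v in _BLOCK_SHAPES.items()}
        self.slices = {}
        off = 0
        for name, shp in self.shapes.items():
            size = int(np.prod(shp)) if shp else 1
            self.slices[name] = slice(off, off + size)
            off += size
        self.size = off

    def pack(self, P: dict) -> np.ndarray:
        C = np.asarray(P["phi"]).shape[0]
        return np.concatenate(
            [np.asarray(P[name]).reshape(C, -1) for name in self.shapes],
            axis=1)

    def extract(self, values: np.ndarray, name: str) -> np.ndarray:
        """Slice draws ``(..., K)`` down to ``(..., *shape)`` for one block."""
        shp = self.shapes[name]
        block = values[..., self.slices[name]]
        return block.reshape(values.shape[:-1] + shp) if shp else block[..., 0]


class PosteriorSamples:
    """Retained post-burn-in, thinned draws from all chains."""

    def __init__(self, values, log_post, layout, sites, samples, years,
                 first_year, options: ProcessOptions, config: ChainConfig,
                 acceptance: dict):
        self.values = values            # (chains, draws, n_params)
        self.log_post = log_post        # (chains, draws)
        self.layout = layout
        self.sites = np.asarray(sites)
        self.samples = np.asarray(samples)
        self.years = np.asarray(years)
        self.first_year = np.asarray(first_year)
        self.options = options
        self.config = config
        self.acceptance = acceptance

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one block, shape ``(chains, draws, *block_shape)``."""
        return self.layout.extract(self.values, name)

    def flat(self, name: str) -> np.ndarray:
        arr = self.get(name)
        return arr.reshape((-1,) + arr.shape[2:])

    def state_at(self, chain: int, draw: int) -> ModelState:
        P = {name: self.layout.extract(self.values[chain, draw], name)
             for name in self.layout.shapes}
        return ModelState(
            phi=float(P["phi"]), p_theta=P["p_theta"], p_kappa=P["p_kappa"],
            k_theta=float(P["k_theta"]), k_kappa=float(P["k_kappa"]),
            N_mean=P["N_mean"], s=float(P["s"]), N=P["N"],
            theta=P["theta"], kappa=P["kappa"], Iprev=P["poolI"],
            Mprev=P["poolM"], Hprev=P["poolH"], kappa0=P["kappa0"],
            sites=self.sites, years=self.years, first_year=self.first_year)

    # -- summaries ---------------------------------------------------------

    def quantity_names(self, include_per_sample: bool = False) -> list[str]:
        names = []
        for name, shp in self.layout.shapes.items():
            if shp == ():
                names.append(name)
            elif len(shp) == 2 and name != "kappa0":
                for i, site in enumerate(self.sites):
                    for t, year in enumerate(self.years):
                        names.append(f"{name}[{site},{year}]")
            elif include_per_sample:
                if name == "kappa0":
                    for i, site in enumerate(self.sites):
                        for j, sm in enumerate(self.samples):
                            names.append(f"kappa0[{site},{sm}]")
                else:
                    for i, site in enumerate(self.sites):
                        for j, sm in enumerate(self.samples):
                            for t, year in enumerate(self.years):
                                names.append(f"{name}[{site},{sm},{year}]")
        return names

    def trace(self, quantity: str) -> np.ndarray:
        """(chains, draws) trace for a label from :meth:`quantity_names`."""
        if "[" in quantity:
            name, rest = quantity.split("[", 1)
            idx = rest.rstrip("]").split(",")
            arr = self.get(name)
            if name == "kappa0":
                i = int(np.nonzero(self.sites == type(self.sites[0])(idx[0]))[0][0])
                j = int(np.nonzero(self.samples == type(self.samples[0])(idx[1]))[0][0])
                return arr[:, :, i, j]
            i = int(np.nonzero(self.sites == type(self.sites[0])(idx[0]))[0][0])
            if len(idx) == 2:
                t = int(np.nonzero(self.years == int(idx[1]))[0][0])
                return arr[:, :, i, t]
            j = int(np.nonzero(self.samples == type(self.samples[0])(idx[1]))[0][0])
            t = int(np.nonzero(self.years == int(idx[2]))[0][0])
            return arr[:, :, i, j, t]
        return self.get(quantity)

    def summary(self, quantities=None, mass: float = 0.95) -> pd.DataFrame:
        """Posterior mean, HPD bounds, R-hat and effective sample size."""
        import arviz as az
        if quantities is None:
            quantities = self.quantity_names(include_per_sample=False)
        rows = []
        for q in quantities:
            tr = self.trace(q)
            lo, hi = hpd_interval(tr, mass=mass)
            if self.n_chains >= 2 and tr.shape[1] >= 2 and tr.std() > 0:
                rhat = gelman_rubin(tr)
            else:
                rhat = float("nan")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ess = float(az.ess(np.asarray(tr)))
            rows.append((q, float(tr.mean()), lo, hi, rhat, ess))
        return pd.DataFrame(
            rows, columns=["quantity", "mean", "hpd_lower", "hpd_upper",
                           "rhat", "ess"])

    def to_frame(self, include_per_sample: bool = False) -> pd.DataFrame:
        """Tidy (chain, draw, quantity, value) table of retained draws."""
        names = self.quantity_names(include_per_sample)
        frames = []
        for q in names:
            tr = self.trace(q)
            C, D = tr.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(C), D),
                "draw": np.tile(np.arange(D), C),
                "quantity": q,
                "value": tr.ravel()}))
        return pd.concat(frames, ignore_index=True)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "options": asdict(self.options),
            "config": {k: v for k, v in asdict(self.config).items()
                       if k != "step_scales"},
            "acceptance": self.acceptance,
        }
        np.savez_compressed(
            path, values=self.values, log_post=self.log_post,
            sites=self.sites, samples=self.samples, years=self.years,
            first_year=self.first_year, meta=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            sites, samples, years = z["sites"], z["samples"], z["years"]
            layout = ParamLayout(len(sites), len(samples), len(years))
            return cls(values=z["values"], log_post=z["log_post"],
                       layout=layout, sites=sites, samples=samples,
                       years=years, first_year=z["first_year"],
                       options=ProcessOptions(**meta["options"]),
                       config=ChainConfig(**meta["config"]),
                       acceptance=meta["acceptance"])


# --------------------------------------------------------------------------
# the model-specific sampler
# --------------------------------------------------------------------------

def _logit_jac(x):
    return np.log(x) + np.log1p(-x)


class CocoonSampler:
    """Block random-walk MH over the chain-stacked cocoon model state.

    ``counts`` may also be a sequence of same-shaped datasets: they are then
    fitted simultaneously, each with its own ``config.n_chains`` chains
    stacked along the leading axis (chains never interact, so every dataset
    still receives a valid posterior sample).  This amortizes the sweep
    overhead across replicate studies in simulation experiments.
    """

    def __init__(self, counts, priors=None, config: ChainConfig | None = None,
                 use_numba: bool = True):
        single = isinstance(counts, CocoonCounts)
        self.datasets = [counts] if single else list(counts)
        self._single = single
        if not self.datasets:
            raise ValidationError("need at least one dataset")
        if priors is None:
            priors_list = [PriorSpec.from_counts(d) for d in self.datasets]
        elif isinstance(priors, PriorSpec):
            if not single:
                raise ValidationError("one PriorSpec per dataset required")
            priors_list = [priors]
        else:
            priors_list = list(priors)
        if len(priors_list) != len(self.datasets):
            raise ValidationError("one PriorSpec per dataset required")
        if config is None:
            config = ChainConfig()
        shape0 = self.datasets[0].shape
        for d, p in zip(self.datasets[1:], priors_list[1:]):
            if d.shape != shape0:
                raise ValidationError("stacked datasets must share one shape")
            if not np.array_equal(priors_list[0].first_year, p.first_year):
                raise ValidationError("stacked datasets must share year runs")
        self.counts = self.datasets[0]
        self.priors = priors_list[0]
        self.priors_list = priors_list
        self.config = config
        self.opts = self.priors.options
        self.S, self.J, self.T = shape0
        nc, G = config.n_chains, len(self.datasets)
        self.C = nc * G

        def _stack(per_dataset):         # (G items) -> (C, ...) chain-major
            return np.repeat(np.stack(per_dataset, axis=0), nc, axis=0)

        self.yI = _stack([d.I.astype(float) for d in self.datasets])
        self.yM = _stack([d.M.astype(float) for d in self.datasets])
        self.yH = _stack([d.H.astype(float) for d in self.datasets])
        self.mask = _stack([d.mask.astype(float) for d in self.datasets])
        self.first = self.priors.first_year
        # pool gamma priors broadcast to (C, S, 1, T) per category
        self.pool_a = [_stack([p.pool_shape[:, None, :, c] for p in priors_list])
                       for c in range(3)]
        self.pool_b = [_stack([p.pool_rate[:, None, :, c] for p in priors_list])
                       for c in range(3)]
        self.rng = np.random.default_rng(config.seed)
        self.layout = ParamLayout(self.S, self.J, self.T)
        self.firstb = np.ascontiguousarray(self.first, dtype=np.bool_)
        # pool priors stacked (3, C, S, T) for the compiled kernels
        self._pa = np.ascontiguousarray(
            np.stack([a[:, :, 0, :] for a in self.pool_a]))
        self._pb = np.ascontiguousarray(
            np.stack([b[:, :, 0, :] for b in self.pool_b]))
        self.P = self._initial_state()
        self.lstep = self._initial_steps()
        self.step = {k: np.exp(v) for k, v in self.lstep.items()}
        self._refresh_caches()
        self._acc = {}
        self._acc_n = {}
        self._use_numba = bool(use_numba)
        if self._use_numba:
            try:
                from . import _kernels
                self._nk = _kernels
            except ImportError:         # pragma: no cover - numba missing
                self._use_numba = False

    def _refresh_caches(self):
        """Log-space caches of the latent state, maintained by the kernels."""
        P = self.P
        with np.errstate(divide="ignore"):
            self.LN = np.log(P["N"])
            self.LTH = np.log(P["theta"])
            self.L1TH = np.log1p(-P["theta"])
            self.LKA = np.log(P["kappa"])
            self.L1KA = np.log1p(-P["kappa"])
            self.LK0 = np.log(P["kappa0"])
            self.L1K0 = np.log1p(-P["kappa0"])
            firstb = self.first[None, :, None, :]
            self.LPI = np.where(firstb & self.opts.zero_history, 0.0,
                                np.log(np.where(P["poolI"] > 0, P["poolI"], 1.0)))
            self.LPM = np.where(firstb & self.opts.zero_history, 0.0,
                                np.log(np.where(P["poolM"] > 0, P["poolM"], 1.0)))
            self.LPH = np.where(firstb & self.opts.zero_history, 0.0,
                                np.log(np.where(P["poolH"] > 0, P["poolH"], 1.0)))
        for name in ("LPI", "LPM", "LPH"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name)))

    # -- state and steps ---------------------------------------------------

    def _initial_state(self) -> dict:
        C, S, J, T = self.C, self.S, self.J, self.T
        rng = self.rng
        mI = np.where(self.mask > 0, self.yI, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            site_year_I = np.nanmean(mI, axis=2)        # over samples -> (C, S, T)
        site_year_I = np.nan_to_num(site_year_I, nan=0.0)
        P = {
            "phi": rng.uniform(0.2, 0.9, C),
            "s": np.exp(rng.normal(0.0, 0.3, C)),
            "k_theta": 2.0 * np.exp(rng.normal(0.0, 0.3, C)),
            "k_kappa": 2.0 * np.exp(rng.normal(0.0, 0.3, C)),
            "p_theta": rng.uniform(0.05, 0.45, (C, S, T)),
            "p_kappa": rng.uniform(0.05, 0.45, (C, S, T)),
            "N_mean": (site_year_I + 1.0) * np.exp(rng.normal(0, 0.1, (C, S, T))),
            "N": (self.yI + 1.0) * np.exp(rng.normal(0, 0.1, (C, S, J, T))),
            "theta": rng.uniform(0.05, 0.35, (C, S, J, T)),
            "kappa": rng.uniform(0.05, 0.35, (C, S, J, T)),
            "kappa0": rng.uniform(0.05, 0.5, (C, S, J)),
        }
        for c, name in enumerate(("poolI", "poolM", "poolH")):
            mean = self.pool_a[c] / self.pool_b[c]           # (C, S, 1, T)
            P[name] = mean * np.exp(rng.normal(0, 0.2, (C, S, J, T)))
            if self.opts.zero_history:
                # first-year history pools are fixed at zero, not latent
                P[name] = np.where(self.first[None, :, None, :], 0.0, P[name])
        return P

    def _initial_steps(self) -> dict:
        C, S, J, T = self.C, self.S, self.J, self.T
        base = {
            "cells": (-1.2, (C, S, J, T)),
            "pools": (-0.7, (C, S, J, T)),
            "kappa0": (-0.7, (C, S, J)),
            "p_theta": (-1.2, (C, S, T)),
            "p_kappa": (-1.2, (C, S, T)),
            "N_mean": (-1.6, (C, S, T)),
            "phi": (-3.0, (C,)),
            "s": (-1.2, (C,)),
            "k_theta": (-1.2, (C,)),
            "k_kappa": (-1.2, (C,)),
        }
        out = {}
        for name, (lv, shp) in base.items():
            scale = self.config.step_scales.get(name)
            out[name] = np.full(shp, math.log(scale) if scale else lv)
        return out

    # -- densities ---------------------------------------------------------

    def _lambda(self, P):
        return expected_counts_grid(
            P["phi"], P["N"], P["theta"], P["kappa"], P["kappa0"],
            P["poolI"], P["poolM"], P["poolH"], self.first, self.opts)

    def _loglik(self, P) -> np.ndarray:
        lam_I, lam_M, lam_H = self._lambda(P)
        m = self.mask
        ll = ((xlogy(self.yI, lam_I) - lam_I - gammaln(self.yI + 1)) * m
              + (xlogy(self.yM, lam_M) - lam_M - gammaln(self.yM + 1)) * m
              + (xlogy(self.yH, lam_H) - lam_H - gammaln(self.yH + 1)) * m)
        return ll.sum(axis=(1, 2, 3))

    def _logprior(self, P) -> np.ndarray:
        pri = self.priors
        out = positive_logpdf(P["k_theta"], pri.k_prior)
        out = out + positive_logpdf(P["k_kappa"], pri.k_prior)
        out = out + positive_logpdf(P["s"], pri.s_prior)
        out = out + positive_logpdf(P["N_mean"], pri.n_mean_prior).sum(axis=(1, 2))
        k_th = P["k_theta"][:, None, None, None]
        p_th = P["p_theta"][:, :, None, :]
        out = out + _beta_lp(P["theta"], k_th * p_th,
                             k_th * (1 - p_th)).sum(axis=(1, 2, 3))
        k_ka = P["k_kappa"][:, None, None, None]
        p_ka = P["p_kappa"][:, :, None, :]
        out = out + _beta_lp(P["kappa"], k_ka * p_ka,
                             k_ka * (1 - p_ka)).sum(axis=(1, 2, 3))
        a_N = P["N_mean"][:, :, None, :] / P["s"][:, None, None, None]
        b_N = 1.0 / P["s"][:, None, None, None]
        out = out + _gamma_lp(P["N"], a_N, b_N).sum(axis=(1, 2, 3))
        firstb = self.first[None, :, None, :]
        for c, name in enumerate(("poolI", "poolM", "poolH")):
            term = _gamma_lp(P[name], self.pool_a[c], self.pool_b[c])
            if self.opts.zero_history:
                term = np.where(firstb, 0.0, term)
            out = out + term.sum(axis=(1, 2, 3))
        return out

    def _jacobian(self, P) -> np.ndarray:
        """Total log |dx/dz| of the sampling transform, per chain."""
        out = _logit_jac(P["phi"])
        out = out + np.log(P["s"]) + np.log(P["k_theta"]) + np.log(P["k_kappa"])
        out = out + _logit_jac(P["p_theta"]).sum(axis=(1, 2))
        out = out + _logit_jac(P["p_kappa"]).sum(axis=(1, 2))
        out = out + np.log(P["N_mean"]).sum(axis=(1, 2))
        out = out + np.log(P["N"]).sum(axis=(1, 2, 3))
        out = out + _logit_jac(P["theta"]).sum(axis=(1, 2, 3))
        out = out + _logit_jac(P["kappa"]).sum(axis=(1, 2, 3))
        out = out + _logit_jac(P["kappa0"]).sum(axis=(1, 2))
        firstb = self.first[None, :, None, :]
        with np.errstate(divide="ignore"):
            for name in ("poolI", "poolM", "poolH"):
                term = np.log(P[name])
                if self.opts.zero_history:
                    term = np.where(firstb, 0.0, term)
                out = out + term.sum(axis=(1, 2, 3))
        return out

    def _logpost_z(self, P) -> np.ndarray:
        return self._loglik(P) + self._logprior(P) + self._jacobian(P)

    def _lik_delta(self, P2, lam):
        """Per-observation log-likelihood change arrays (dI, dM, dH)."""
        lam2 = self._lambda(P2)
        m = self.mask
        dI = (xlogy(self.yI, lam2[0]) - lam2[0]
              - xlogy(self.yI, lam[0]) + lam[0]) * m
        dM = (xlogy(self.yM, lam2[1]) - lam2[1]
              - xlogy(self.yM, lam[1]) + lam[1]) * m
        dH = (xlogy(self.yH, lam2[2]) - lam2[2]
              - xlogy(self.yH, lam[2]) + lam[2]) * m
        return dI, dM, dH

    # -- block updates -----------------------------------------------------

    def _record(self, name, acc):
        self._acc[name] = self._acc.get(name, 0.0) + float(np.mean(acc))
        self._acc_n[name] = self._acc_n.get(name, 0) + 1

    def _update_cells(self, parity: int, gain=None, force_all=False,
                      noise=None, unif=None):
        P = self.P
        C, S, J, T = self.C, self.S, self.J, self.T
        if noise is None:
            noise = self.rng.standard_normal((3, C, S, J, T))
        if unif is None:
            unif = self.rng.random((C, S, J, T))
        tsel = np.arange(parity, self.T, 2)
        if tsel.size == 0:
            return None
        step = np.exp(self.lstep["cells"][..., tsel])
        N, th, ka = P["N"][..., tsel], P["theta"][..., tsel], P["kappa"][..., tsel]
        zN, zt, zk = np.log(N), logit(th), logit(ka)
        e = noise[..., tsel]
        zN2, zt2, zk2 = zN + step * e[0], zt + step * e[1], zk + step * e[2]
        N2, th2, ka2 = np.exp(zN2), expit(zt2), expit(zk2)
        bad = ((th2 <= 0) | (th2 >= 1) | (ka2 <= 0) | (ka2 >= 1)
               | ~np.isfinite(N2) | (N2 <= 0))

        P2 = dict(P)
        for name, new in (("N", N2), ("theta", th2), ("kappa", ka2)):
            arr = P[name].copy()
            arr[..., tsel] = new
            P2[name] = arr
        dI, dM, dH = self._lik_delta(P2, self._lambda(P))
        delta = dI[..., tsel] + dM[..., tsel]
        nxt = tsel + 1 < self.T
        if nxt.any():
            dnext = dM + dH
            add = np.zeros_like(delta)
            add[..., nxt] = dnext[..., tsel[nxt] + 1]
            delta = delta + add

        with np.errstate(divide="ignore", invalid="ignore"):
            s_ = P["s"][:, None, None, None]
            aN = P["N_mean"][:, :, None, tsel] / s_
            delta += (aN - 1) * (zN2 - zN) - (N2 - N) / s_
            kth = P["k_theta"][:, None, None, None]
            pth = P["p_theta"][:, :, None, tsel]
            delta += ((kth * pth - 1) * (np.log(th2) - np.log(th))
                      + (kth * (1 - pth) - 1) * (np.log1p(-th2) - np.log1p(-th)))
            kka = P["k_kappa"][:, None, None, None]
            pka = P["p_kappa"][:, :, None, tsel]
            delta += ((kka * pka - 1) * (np.log(ka2) - np.log(ka))
                      + (kka * (1 - pka) - 1) * (np.log1p(-ka2) - np.log1p(-ka)))
            delta += (zN2 - zN)
            delta += _logit_jac(th2) - _logit_jac(th)
            delta += _logit_jac(ka2) - _logit_jac(ka)
        delta = np.where(bad, -np.inf, delta)

        if force_all:
            for name in ("N", "theta", "kappa"):
                P[name] = P2[name]
            return delta
        acc = np.log(unif[..., tsel]) < delta
        for name, new, cur in (("N", N2, N), ("theta", th2, th), ("kappa", ka2, ka)):
            P[name][..., tsel] = np.where(acc, new, cur)
        if gain is not None:
            self.lstep["cells"][..., tsel] += gain * (acc - self.config.target_block)
        self._record(f"cells_{'even' if parity == 0 else 'odd'}", acc)
        return acc

    def _update_pools(self, gain=None, force_all=False,
                      noise=None, noise0=None, unif=None):
        P = self.P
        C, S, J, T = self.C, self.S, self.J, self.T
        zero_hist = self.opts.zero_history
        isfirst = self.first[None, :, None, :]
        if noise is None:
            noise = self.rng.standard_normal((3, C, S, J, T))
        if not zero_hist and noise0 is None:
            noise0 = self.rng.standard_normal((C, S, J))
        if unif is None:
            unif = self.rng.random((C, S, J, T))
        step = np.exp(self.lstep["pools"])
        cur = [P["poolI"], P["poolM"], P["poolH"]]
        safe = ([np.where(isfirst, 1.0, c) for c in cur] if zero_hist else cur)
        z = [np.log(sc) for sc in safe]
        z2 = [z[c] + step * noise[c] for c in range(3)]
        with np.errstate(over="ignore"):       # overflow -> rejected below
            new = [np.exp(zz) for zz in z2]
        if zero_hist:
            # first-year pools are fixed at zero; never propose a change there
            new = [np.where(isfirst, cur[c], new[c]) for c in range(3)]

        P2 = dict(P)
        for c, name in enumerate(("poolI", "poolM", "poolH")):
            P2[name] = new[c]
        if not zero_hist:
            zk0 = logit(P["kappa0"])
            zk02 = zk0 + np.exp(self.lstep["kappa0"]) * noise0
            k02 = expit(zk02)
            bad0 = (k02 <= 0) | (k02 >= 1)
            P2["kappa0"] = np.where(bad0, P["kappa0"], k02)
        _, dM, dH = self._lik_delta(P2, self._lambda(P))
        delta = dM + dH
        with np.errstate(divide="ignore", invalid="ignore"):
            for c in range(3):
                a, b = self.pool_a[c], self.pool_b[c]
                dpool = (a - 1) * (z2[c] - z[c]) - b * (new[c] - cur[c])
                dpool += z2[c] - z[c]            # log-transform jacobian
                if zero_hist:
                    dpool = np.where(isfirst, 0.0, dpool)
                delta += dpool
            if not zero_hist:
                djk0 = np.where(bad0, -np.inf,
                                _logit_jac(k02) - _logit_jac(P["kappa0"]))
                delta = delta + np.where(isfirst, djk0[..., None], 0.0)
        bad = np.zeros(delta.shape, dtype=bool)
        for c in range(3):
            bad |= ~np.isfinite(new[c]) | (new[c] <= 0)
        if zero_hist:
            bad &= ~np.broadcast_to(isfirst, bad.shape)  # first cells unchanged
        delta = np.where(bad, -np.inf, delta)

        if force_all:
            for c, name in enumerate(("poolI", "poolM", "poolH")):
                P[name] = new[c]
            if not zero_hist:
                P["kappa0"] = P2["kappa0"]
            return delta
        acc = np.log(unif) < delta
        for c, name in enumerate(("poolI", "poolM", "poolH")):
            P[name] = np.where(acc, new[c], cur[c])
        if not zero_hist:
            acc0 = np.any(acc & isfirst, axis=-1)
            P["kappa0"] = np.where(acc0, P2["kappa0"], P["kappa0"])
        if gain is not None:
            self.lstep["pools"] += gain * (acc - self.config.target_block)
            if not zero_hist:
                self.lstep["kappa0"] += gain * (acc0 - self.config.target_block)
        self._record("pools", acc)
        return acc

    def _update_site_year_rate(self, name: str, gain=None, force_all=False,
                               noise=None, unif=None):
        """Update p_theta or p_kappa (site-year mean predation rates)."""
        P = self.P
        if noise is None:
            noise = self.rng.standard_normal((self.C, self.S, self.T))
        if unif is None:
            unif = self.rng.random((self.C, self.S, self.T))
        which = "theta" if name == "p_theta" else "kappa"
        k = P["k_theta" if which == "theta" else "k_kappa"][:, None, None]
        lat = P[which]
        p = P[name]
        z = logit(p)
        step = np.exp(self.lstep[name])
        z2 = z + step * noise
        p2 = expit(z2)
        bad = (p2 <= 0) | (p2 >= 1)
        Slog = np.log(lat).sum(axis=2)
        Slog1m = np.log1p(-lat).sum(axis=2)
        a, b = k * p, k * (1 - p)
        a2, b2 = k * p2, k * (1 - p2)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = (self.J * (gammaln(a) + gammaln(b) - gammaln(a2) - gammaln(b2))
                     + (a2 - a) * Slog + (b2 - b) * Slog1m
                     + _logit_jac(p2) - _logit_jac(p))
        delta = np.where(bad, -np.inf, delta)
        if force_all:
            P[name] = np.where(bad, p, p2)
            return delta
        acc = np.log(unif) < delta
        P[name] = np.where(acc, p2, p)
        if gain is not None:
            self.lstep[name] += gain * (acc - self.config.target_scalar)
        self._record(name, acc)
        return acc

    def _update_N_mean(self, gain=None, force_all=False, noise=None, unif=None):
        P = self.P
        if noise is None:
            noise = self.rng.standard_normal((self.C, self.S, self.T))
        if unif is None:
            unif = self.rng.random((self.C, self.S, self.T))
        s = P["s"][:, None, None]
        Nm = P["N_mean"]
        z = np.log(Nm)
        z2 = z + np.exp(self.lstep["N_mean"]) * noise
        Nm2 = np.exp(z2)
        SlogN = np.log(P["N"]).sum(axis=2)
        a, a2 = Nm / s, Nm2 / s
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = (self.J * ((a2 - a) * np.log(1.0 / s)
                               - (gammaln(a2) - gammaln(a)))
                     + (a2 - a) * SlogN
                     + positive_logpdf(Nm2, self.priors.n_mean_prior)
                     - positive_logpdf(Nm, self.priors.n_mean_prior)
                     + (z2 - z))
        bad = ~np.isfinite(Nm2) | (Nm2 <= 0)
        delta = np.where(bad, -np.inf, delta)
        if force_all:
            P["N_mean"] = np.where(bad, Nm, Nm2)
            return delta
        acc = np.log(unif) < delta
        P["N_mean"] = np.where(acc, Nm2, Nm)
        if gain is not None:
            self.lstep["N_mean"] += gain * (acc - self.config.target_scalar)
        self._record("N_mean", acc)
        return acc

    def _update_phi(self, gain=None, force_all=False, noise=None, unif=None):
        P = self.P
        if noise is None:
            noise = self.rng.standard_normal(self.C)
        if unif is None:
            unif = self.rng.random(self.C)
        phi = P["phi"]
        z = logit(phi)
        z2 = z + np.exp(self.lstep["phi"]) * noise
        phi2 = expit(z2)
        bad = (phi2 <= 0) | (phi2 >= 1)
        P2 = dict(P)
        P2["phi"] = np.where(bad, phi, phi2)
        _, dM, dH = self._lik_delta(P2, self._lambda(P))
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = ((dM + dH).sum(axis=(1, 2, 3))
                     + _logit_jac(np.where(bad, phi, phi2)) - _logit_jac(phi))
        delta = np.where(bad, -np.inf, delta)
        if force_all:
            P["phi"] = P2["phi"]
            return delta
        acc = np.log(unif) < delta
        P["phi"] = np.where(acc, phi2, phi)
        if gain is not None:
            self.lstep["phi"] += gain * (acc - self.config.target_scalar)
        self._record("phi", acc)
        return acc

    def _N_prior_total(self, s) -> np.ndarray:
        """Sum of the per-sample gamma(N | N_mean/s, 1/s) log-densities."""
        P = self.P
        a = P["N_mean"] / s[:, None, None]              # (C, S, T)
        SlogN = np.log(P["N"]).sum(axis=2)
        SN = P["N"].sum(axis=2)
        term = (self.J * (a * np.log(1.0 / s[:, None, None]) - gammaln(a))
                + (a - 1) * SlogN - SN / s[:, None, None])
        return term.sum(axis=(1, 2))

    def _update_s(self, gain=None, force_all=False, noise=None, unif=None):
        P = self.P
        if noise is None:
            noise = self.rng.standard_normal(self.C)
        if unif is None:
            unif = self.rng.random(self.C)
        s = P["s"]
        z = np.log(s)
        z2 = z + np.exp(self.lstep["s"]) * noise
        s2 = np.exp(z2)
        bad = ~np.isfinite(s2) | (s2 <= 0)
        s2 = np.where(bad, s, s2)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = (self._N_prior_total(s2) - self._N_prior_total(s)
                     + positive_logpdf(s2, self.priors.s_prior)
                     - positive_logpdf(s, self.priors.s_prior)
                     + (z2 - z))
        delta = np.where(bad, -np.inf, delta)
        if force_all:
            P["s"] = s2
            return delta
        acc = np.log(unif) < delta
        P["s"] = np.where(acc, s2, s)
        if gain is not None:
            self.lstep["s"] += gain * (acc - self.config.target_scalar)
        self._record("s", acc)
        return acc

    def _beta_prior_total(self, k, which: str) -> np.ndarray:
        P = self.P
        p = P["p_theta" if which == "theta" else "p_kappa"]  # (C, S, T)
        lat = P[which]
        kk = k[:, None, None]
        Slog = np.log(lat).sum(axis=2)
        Slog1m = np.log1p(-lat).sum(axis=2)
        term = (self.J * (gammaln(kk) - gammaln(kk * p) - gammaln(kk * (1 - p)))
                + (kk * p - 1) * Slog + (kk * (1 - p) - 1) * Slog1m)
        return term.sum(axis=(1, 2))

    def _update_k(self, which: str, gain=None, force_all=False,
                  noise=None, unif=None):
        P = self.P
        if noise is None:
            noise = self.rng.standard_normal(self.C)
        if unif is None:
            unif = self.rng.random(self.C)
        name = "k_theta" if which == "theta" else "k_kappa"
        k = P[name]
        z = np.log(k)
        z2 = z + np.exp(self.lstep[name]) * noise
        k2 = np.exp(z2)
        bad = ~np.isfinite(k2) | (k2 <= 0)
        k2 = np.where(bad, k, k2)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = (self._beta_prior_total(k2, which)
                     - self._beta_prior_total(k, which)
                     + positive_logpdf(k2, self.priors.k_prior)
                     - positive_logpdf(k, self.priors.k_prior)
                     + (z2 - z))
        delta = np.where(bad, -np.inf, delta)
        if force_all:
            P[name] = k2
            return delta
        acc = np.log(unif) < delta
        P[name] = np.where(acc, k2, k)
        if gain is not None:
            self.lstep[name] += gain * (acc - self.config.target_scalar)
        self._record(name, acc)
        return acc

    # -- sweep and run -----------------------------------------------------

    def _record_counts(self, name, n_acc, n_total):
        self._acc[name] = self._acc.get(name, 0.0) + n_acc / max(n_total, 1)
        self._acc_n[name] = self._acc_n.get(name, 0) + 1

    def _sweep_numba(self, gain=None) -> None:
        """Compiled sweep; consumes the RNG stream exactly like the
        reference numpy updates so both paths are comparable."""
        nk = self._nk
        P = self.P
        r = self.rng
        C, S, J, T = self.C, self.S, self.J, self.T
        g = 0.0 if gain is None else float(gain)
        opts = self.opts
        flags = (opts.phi_on_fresh_empties, opts.zero_history,
                 opts.lambda_floor)
        for parity in (0, 1):
            noise = r.standard_normal((3, C, S, J, T))
            unif = r.random((C, S, J, T))
            n_acc, n_tot = nk.cells_update(
                parity, P["N"], P["theta"], P["kappa"], P["kappa0"],
                P["poolI"], P["poolM"], P["poolH"],
                self.LN, self.LTH, self.L1TH, self.LKA, self.L1KA,
                P["phi"], P["s"], P["N_mean"], P["k_theta"], P["k_kappa"],
                P["p_theta"], P["p_kappa"],
                self.yI, self.yM, self.yH, self.mask, self.firstb,
                self.lstep["cells"], self.step["cells"], noise, unif,
                g, self.config.target_block, *flags)
            self._record_counts(f"cells_{'even' if parity == 0 else 'odd'}",
                                n_acc, n_tot)
        noise = r.standard_normal((3, C, S, J, T))
        noise0 = (r.standard_normal((C, S, J)) if not opts.zero_history
                  else np.zeros((C, S, J)))
        unif = r.random((C, S, J, T))
        n_acc, n_tot = nk.pools_update(
            P["poolI"], P["poolM"], P["poolH"], P["kappa0"],
            P["N"], P["theta"], P["kappa"], P["phi"],
            self.LPI, self.LPM, self.LPH, self.LK0, self.L1K0,
            self._pa, self._pb, self.yM, self.yH, self.mask, self.firstb,
            self.lstep["pools"], self.step["pools"],
            self.lstep["kappa0"], self.step["kappa0"],
            noise, noise0, unif, g, self.config.target_block, *flags)
        self._record_counts("pools", n_acc, n_tot)
        for pname, which in (("p_theta", "theta"), ("p_kappa", "kappa")):
            noise = r.standard_normal((C, S, T))
            unif = r.random((C, S, T))
            lat_l = self.LTH if which == "theta" else self.LKA
            lat_l1 = self.L1TH if which == "theta" else self.L1KA
            kname = "k_theta" if which == "theta" else "k_kappa"
            n_acc, n_tot = nk.site_rate_update(
                P[pname], P[kname], lat_l, lat_l1,
                self.lstep[pname], self.step[pname], noise, unif,
                g, self.config.target_scalar)
            self._record_counts(pname, n_acc, n_tot)
        noise = r.standard_normal((C, S, T))
        unif = r.random((C, S, T))
        fam, pa, pb = _prior_code(self.priors.n_mean_prior)
        n_acc, n_tot = nk.n_mean_update(
            P["N_mean"], P["s"], self.LN,
            self.lstep["N_mean"], self.step["N_mean"], noise, unif,
            g, self.config.target_scalar, fam, pa, pb)
        self._record_counts("N_mean", n_acc, n_tot)
        noise = r.standard_normal(C)
        unif = r.random(C)
        n_acc, n_tot = nk.phi_update(
            P["phi"], P["N"], P["theta"], P["kappa"], P["kappa0"],
            P["poolI"], P["poolM"], P["poolH"],
            self.yM, self.yH, self.mask, self.firstb,
            self.lstep["phi"], self.step["phi"], noise, unif,
            g, self.config.target_scalar, *flags)
        self._record_counts("phi", n_acc, n_tot)
        noise = r.standard_normal(C)
        unif = r.random(C)
        fam, pa, pb = _prior_code(self.priors.s_prior)
        n_acc, n_tot = nk.s_update(
            P["s"], P["N_mean"], P["N"], self.LN,
            self.lstep["s"], self.step["s"], noise, unif,
            g, self.config.target_scalar, fam, pa, pb)
        self._record_counts("s", n_acc, n_tot)
        fam, pa, pb = _prior_code(self.priors.k_prior)
        for kname, which in (("k_theta", "theta"), ("k_kappa", "kappa")):
            noise = r.standard_normal(C)
            unif = r.random(C)
            pname = "p_theta" if which == "theta" else "p_kappa"
            lat_l = self.LTH if which == "theta" else self.LKA
            lat_l1 = self.L1TH if which == "theta" else self.L1KA
            n_acc, n_tot = nk.k_update(
                P[kname], P[pname], lat_l, lat_l1,
                self.lstep[kname], self.step[kname], noise, unif,
                g, self.config.target_scalar, fam, pa, pb)
            self._record_counts(kname, n_acc, n_tot)

    def sweep(self, gain=None) -> None:
        """One full iteration: every block updated once, fixed order."""
        if self._use_numba:
            self._sweep_numba(gain)
            return
        self._update_cells(0, gain)
        self._update_cells(1, gain)
        self._update_pools(gain)
        self._update_site_year_rate("p_theta", gain)
        self._update_site_year_rate("p_kappa", gain)
        self._update_N_mean(gain)
        self._update_phi(gain)
        self._update_s(gain)
        self._update_k("theta", gain)
        self._update_k("kappa", gain)

    def acceptance_rates(self) -> dict:
        return {k: self._acc[k] / self._acc_n[k] for k in self._acc}

    def run(self) -> PosteriorSamples:
        cfg = self.config
        lp0 = self._loglik(self.P) + self._logprior(self.P)
        if not np.all(np.isfinite(lp0)):
            raise RuntimeError(
                f"non-finite log posterior at initialization: {lp0}")
        n_keep = cfg.n_retained
        values = np.empty((self.C, n_keep, self.layout.size))
        log_post = np.empty((self.C, n_keep))
        kept = 0
        for it in range(1, cfg.n_iterations + 1):
            gain = None
            if cfg.adapt and it <= cfg.burn_in:
                gain = min(0.3, 2.0 * it ** -0.6)
            self.sweep(gain)
            if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                values[:, kept, :] = self.layout.pack(self.P)
                log_post[:, kept] = self._loglik(self.P) + self._logprior(self.P)
                kept += 1
        assert kept == n_keep
        acc = self.acceptance_rates()
        out = []
        nc = cfg.n_chains
        for g, dataset in enumerate(self.datasets):
            rows = slice(g * nc, (g + 1) * nc)
            out.append(PosteriorSamples(
                values=values[rows], log_post=log_post[rows],
                layout=self.layout, sites=dataset.sites,
                samples=dataset.samples, years=dataset.years,
                first_year=self.first, options=self.opts, config=cfg,
                acceptance=acc))
        return out[0] if self._single else out


def run_chains(counts, priors=None, config: ChainConfig | None = None):
    """Fit the cocoon model by block random-walk MH; see :class:`CocoonSampler`.

    With a single :class:`CocoonCounts` returns one :class:`PosteriorSamples`;
    with a sequence of same-shaped datasets returns one per dataset.
    """
    return CocoonSampler(counts, priors, config).run()


def _prior_code(prior: tuple) -> tuple[int, float, float]:
    family, a, b = prior
    return (0 if family == "gamma" else 1, float(a), float(b))


# fast local helpers (normalized, used by the chain-wise prior)

def _gamma_lp(x, a, b):
    with np.errstate(divide="ignore", invalid="ignore"):
        return a * np.log(b) - gammaln(a) + xlogy(a - 1.0, x) - b * x


def _beta_lp(x, a, b):
    with np.errstate(divide="ignore", invalid="ignore"):
        return (gammaln(a + b) - gammaln(a) - gammaln(b)
                + xlogy(a - 1.0, x) + xlogy(b - 1.0, 1.0 - x))
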