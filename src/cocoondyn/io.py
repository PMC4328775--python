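"""Readers and writers for the delimited-text schemas and YAML configs."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CocoonCounts, PriorSpec, ProcessOptions, ValidationError
from .mcmc import ChainConfig
from .posthoc import validate_defoliation, validate_trap_records
from .simulate import SimTruth, SimulatedDataset


def read_counts(path) -> CocoonCounts:
    """Read and validate a ``site,sample,year,I,M,H`` CSV."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"count file {path} does not exist")
    return CocoonCounts.from_frame(pd.read_csv(path))


def write_counts(counts: CocoonCounts, path) -> None:
    counts.to_frame().to_csv(path, index=False)


def read_trap_records(path) -> pd.DataFrame:
    return validate_trap_records(pd.read_csv(path))


def read_defoliation(path) -> pd.DataFrame:
    return validate_defoliation(pd.read_csv(path))


def write_truth(sim: SimulatedDataset, yaml_path, latents_path=None) -> None:
    """Persist a simulation's generating parameters (YAML) and, optionally,
    its per-cell latent trajectories (CSV)."""
    t = sim.truth
    doc = {
        "phi": float(t.phi),
        "k_theta": float(t.k_theta),
        "k_kappa": float(t.k_kappa),
        "s": float(t.s),
        "n_sites": t.n_sites,
        "n_samples": t.n_samples,
        "n_years": t.n_years,
        "seed": t.seed,
        "warmup_years": t.warmup_years,
        "start_year": t.start_year,
        "p_theta": np.asarray(t.p_theta).tolist(),
        "p_kappa": np.asarray(t.p_kappa).tolist(),
        "N_mean": np.asarray(t.N_mean).tolist(),
        "phi_on_fresh_empties": t.options.phi_on_fresh_empties,
        "zero_history": t.options.zero_history,
    }
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(doc, fh)
    if latents_path is not None:
        sim.truth_frame().to_csv(latents_path, index=False)


def read_truth(yaml_path) -> SimTruth:
    with open(yaml_path) as fh:
        doc = yaml.safe_load(fh)
    options = ProcessOptions(
        phi_on_fresh_empties=doc.pop("phi_on_fresh_empties", True),
        zero_history=doc.pop("zero_history", False))
    for key in ("p_theta", "p_kappa", "N_mean"):
        doc[key] = np.asarray(doc[key], dtype=float)
    return SimTruth(options=options, **doc)


def load_run_config(path) -> dict:
    """Read a YAML config of prior/process/chain overrides.

    Recognized top-level keys: ``process`` (phi_on_fresh_empties,
    zero_history, lambda_floor), ``priors`` (k_prior, s_prior, n_mean_prior,
    init_pool_prior, variance_floor, mean_floor) and ``chains`` (any
    :class:`ChainConfig` field).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out = {"process": doc.get("process", {}) or {},
           "priors": doc.get("priors", {}) or {},
           "chains": doc.get("chains", {}) or {}}
    for prior_key in ("k_prior", "s_prior", "n_mean_prior", "init_pool_prior"):
        if prior_key in out["priors"]:
            fam, a, b = out["priors"][prior_key]
            out["priors"][prior_key] = (str(fam), float(a), float(b))
    return out


def build_priors(counts: CocoonCounts, config: dict | None = None) -> PriorSpec:
    """PriorSpec from counts plus an optional :func:`load_run_config` dict."""
    config = config or {}
    options = ProcessOptions(**config.get("process", {}))
    prior_kwargs = dict(config.get("priors", {}))
    variance_floor = prior_kwargs.pop("variance_floor", 0.25)
    mean_floor = prior_kwargs.pop("mean_floor", 0.1)
    return PriorSpec.from_counts(counts, variance_floor=variance_floor,
                                 mean_floor=mean_floor, options=options,
                                 **prior_kwargs)


def build_chain_config(preset: str = "desk", seed: int = 0,
                       config: dict | None = None) -> ChainConfig:
    overrides = dict((config or {}).get("chains", {}))
    overrides.pop("seed", None)
    if preset == "desk":
        return ChainConfig.desk(seed=seed, **overrides)
    if preset == "paper":
        return ChainConfig.paper_scale(seed=seed, **overrides)
    raise ValidationError(f"unknown preset {preset!r}; use 'desk' or 'paper'")


def load_reference_site_means() -> pd.DataFrame:
    """Packaged per-site mean cocoon counts (per 0.04 m^2 sample) from the
    motivating eight-site, four-year larch-plantation survey.

    Columns: category (I/M/H), generation, site, mean_count.
    """
    with resources.files("cocoondyn.data").joinpath(
            "site_mean_counts.csv").open() as fh:
        return pd.read_csv(fh)
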