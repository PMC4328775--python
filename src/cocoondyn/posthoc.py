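"""Post hoc validity analyses of a fitted cocoon model.

Three checks connect the posterior to independent field evidence: the
site-generation predation summary (including the total cocoon-period rate
rho), beta regressions of estimated predation rates on small-mammal
trap-capture indices, and Pearson correlations of cocoon abundance with
defoliation intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CocoonCounts, ValidationError, total_predation_rate
from .mcmc import PosteriorSamples, hpd_interval

SEASONS = ("spring", "autumn")


@dataclass
class BetaRegressionResult:
    coefficient: float     # slope on the explanatory variable (logit scale)
    p_value: float         # two-sided Wald test of slope = 0
    precision: float       # constant beta precision parameter
    n: int


def squeeze_unit_interval(y: np.ndarray) -> np.ndarray:
    """Shrink proportions off the boundary: ``(y * (n - 1) + 0.5) / n``."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return (y * (n - 1) + 0.5) / n


def beta_regression(x, y) -> BetaRegressionResult:
    """ML beta regression of rates on one covariate (logit mean link).

    Responses must be proportions; exact 0s and 1s are shrunk into the open
    interval with the standard continuity correction before fitting.
    """
    import statsmodels.api as sm
    from statsmodels.othermod.betareg import BetaModel

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.any(y < 0) or np.any(y > 1):
        raise ValidationError("responses must lie in [0, 1]")
    if np.ptp(x) == 0:
        raise ValidationError("explanatory variable has zero variance")
    if np.any(y <= 0) or np.any(y >= 1):
        y = squeeze_unit_interval(y)
    exog = sm.add_constant(x)
    res = BetaModel(y, exog).fit(disp=False)
    return BetaRegressionResult(
        coefficient=float(res.params[1]),
        p_value=float(res.pvalues[1]),
        precision=float(res.params[-1]),
        n=len(x))


def pearson_correlation(a, b) -> tuple[float, float, int]:
    """Product-moment correlation with its two-sided t-test P-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValidationError("need two equal-length 1-D arrays with n >= 3")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), len(a)


# --------------------------------------------------------------------------
# predation summary (site x generation table)
# --------------------------------------------------------------------------

def summarize_predation(samples: PosteriorSamples,
                        mass: float = 0.95) -> pd.DataFrame:
    """Posterior mean and HPD of N, theta, kappa and rho per site-generation.

    ``rho`` is computed draw by draw as the complementary-survival
    combination of the site-year mean rates and then summarized.  The final
    generation's after-sampling rate (and hence rho) has no following year's
    data to constrain it, so those rows carry NA.
    """
    n_mean = samples.get("N_mean")        # (C, D, S, T)
    p_th = samples.get("p_theta")
    p_ka = samples.get("p_kappa")
    rho = total_predation_rate(p_th, p_ka)
    last_t = len(samples.years) - 1
    rows = []
    for i, site in enumerate(samples.sites):
        for t, year in enumerate(samples.years):
            for qname, arr in (("N", n_mean), ("theta", p_th),
                               ("kappa", p_ka), ("rho", rho)):
                if qname in ("kappa", "rho") and t == last_t:
                    rows.append((site, int(year), qname,
                                 np.nan, np.nan, np.nan))
                    continue
                tr = arr[:, :, i, t]
                lo, hi = hpd_interval(tr, mass=mass)
                rows.append((site, int(year), qname, float(tr.mean()), lo, hi))
    return pd.DataFrame(rows, columns=["site", "generation", "quantity",
                                       "mean", "hpd_lower", "hpd_upper"])


# --------------------------------------------------------------------------
# trap captures and defoliation
# --------------------------------------------------------------------------

def validate_trap_records(df: pd.DataFrame) -> pd.DataFrame:
    need = {"site", "year", "season", "captures"}
    if not need.issubset(df.columns):
        raise ValidationError(f"trap table needs columns {sorted(need)}")
    if not df["season"].isin(SEASONS).all():
        bad = df.loc[~df["season"].isin(SEASONS), "season"].iloc[0]
        raise ValidationError(f"unknown season {bad!r}; use {SEASONS}")
    if (df["captures"] < 0).any():
        raise ValidationError("captures must be >= 0")
    return df


def validate_defoliation(df: pd.DataFrame) -> pd.DataFrame:
    need = {"site", "year", "intensity"}
    if not need.issubset(df.columns):
        raise ValidationError(f"defoliation table needs columns {sorted(need)}")
    if ((df["intensity"] < 0) | (df["intensity"] > 100)).any():
        raise ValidationError("intensity must lie in [0, 100] percent")
    return df


def _capture_index(traps: pd.DataFrame) -> pd.DataFrame:
    """Total captures per (year, season) across all trapping sites."""
    return (traps.groupby(["year", "season"], as_index=False)["captures"]
            .sum())


def pair_rates_with_captures(summary: pd.DataFrame, traps: pd.DataFrame,
                             rate: str) -> pd.DataFrame:
    """Pair each site-generation rate with the relevant trap index.

    theta (predation before the October sampling of generation t) pairs with
    the autumn captures of year t; kappa (after sampling) with the following
    spring's captures; rho with the mean of the two.
    """
    if rate not in ("theta", "kappa", "rho"):
        raise ValidationError("rate must be theta, kappa or rho")
    traps = validate_trap_records(traps)
    idx = _capture_index(traps).set_index(["year", "season"])["captures"]

    sub = summary[summary["quantity"] == rate].dropna(subset=["mean"])
    recs = []
    for row in sub.itertuples(index=False):
        t = int(row.generation)
        autumn = idx.get((t, "autumn"))
        spring = idx.get((t + 1, "spring"))
        if rate == "theta":
            x = autumn
        elif rate == "kappa":
            x = spring
        else:
            x = None if (autumn is None or spring is None) else (autumn + spring) / 2.0
        if x is not None:
            recs.append((row.site, t, float(x), float(row.mean)))
    return pd.DataFrame(recs, columns=["site", "generation", "captures", "rate"])


def regress_predation_on_captures(summary: pd.DataFrame,
                                  traps: pd.DataFrame) -> pd.DataFrame:
    """Beta regression of each predation rate on its trap-capture index."""
    rows = []
    for rate in ("theta", "kappa", "rho"):
        paired = pair_rates_with_captures(summary, traps, rate)
        res = beta_regression(paired["captures"].to_numpy(),
                              paired["rate"].to_numpy())
        rows.append((rate, res.coefficient, res.p_value, res.precision, res.n))
    return pd.DataFrame(rows, columns=["rate", "coefficient", "p_value",
                                       "precision", "n"])


def correlate_abundance_with_defoliation(summary: pd.DataFrame,
                                         counts: CocoonCounts,
                                         defoliation: pd.DataFrame,
                                         exclude_sites=()) -> pd.DataFrame:
    """Pearson correlation of N (posterior mean) and observed I site-year
    means with defoliation intensity."""
    defoliation = validate_defoliation(defoliation)
    dmap = defoliation.set_index(["site", "year"])["intensity"]

    n_sub = summary[summary["quantity"] == "N"]
    rows = []
    for label in ("N", "I"):
        xs, ys = [], []
        for i, site in enumerate(counts.sites):
            if site in exclude_sites:
                continue
            for t, year in enumerate(counts.years):
                key = (site, int(year))
                if key not in dmap.index:
                    continue
                if label == "N":
                    sel = n_sub[(n_sub["site"] == site)
                                & (n_sub["generation"] == int(year))]
                    if sel.empty:
                        continue
                    val = float(sel["mean"].iloc[0])
                else:
                    present = counts.mask[i, :, t]
                    if not present.any():
                        continue
                    val = float(counts.I[i, present, t].mean())
                xs.append(float(dmap[key]))
                ys.append(val)
        r, p, n = pearson_correlation(np.asarray(xs), np.asarray(ys))
        rows.append((label, r, p, n))
    return pd.DataFrame(rows, columns=["value", "r", "p", "n"])
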