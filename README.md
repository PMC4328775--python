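# cocoondyn

Hierarchical Bayesian estimation of sawfly cocoon abundance and
small-mammal predation from annual one-time soil sampling.

## The problem

Larch sawfly (*Pristiphora erichsonii*) larvae drop to the soil and spin
cocoons in which they overwinter. Small mammals (field mice, voles) open
and empty these cocoons, and predation is often the dominant mortality of
the cocoon stage — but it cannot be observed directly:

* larvae do not all spin at the same time, and predation starts
  immediately, so the number of *newly spun* cocoons is never observable;
* empty shells persist in the soil for years, and this year's empties are
  indistinguishable from last year's by eye.

An annual mid-October soil sample therefore yields only three counts per
0.04 m² core: unopened cocoons `I` (current generation only),
predation-emptied shells `M` (accumulated across generations), and shells
emptied by everything else `H` (emergence, parasitoids, disease; previous
generations only). `cocoondyn` estimates what those counts cannot show
directly: the newly spun cocoons `N` and the predation rates before (θ)
and after (κ) the October sampling, per site and generation, for anyone
building life tables of soil-cocooning Hymenoptera or Lepidoptera.

## The model

For sample *j* at site *i* in year *t*, counts are Poisson with means
built from a latent cohort recursion:

```
I_ijt ~ Poisson(λI),   λI = N_ijt (1 − θ_ijt)
M_ijt ~ Poisson(λM),   λM = N_ijt θ_ijt + φ (κ_ij,t−1 I′ + M′)
H_ijt ~ Poisson(λH),   λH = φ ((1 − κ_ij,t−1) I′ + H′)
```

where `I′, M′, H′` are latent pools of the previous year's cocoons still
present in this year's core (given moment-matched gamma priors built from
the previous year's observed counts), and φ ∈ [0, 1] is the annual
remaining rate of empty shells. Per-sample rates are beta-distributed
around site-year means, `θ_ijt ~ Beta(k_θ p_θ,it, k_θ (1 − p_θ,it))` and
likewise for κ; per-sample cocoon rain is
`N_ijt ~ Gamma(N_it / s, 1/s)`. Hyperpriors are U(0, 1) for rates,
Gamma(1, 1) for the beta dispersions and InvGamma(0.001, 0.001) for the
positive scales. The total cocoon-period predation rate is
`ρ = 1 − (1 − θ)(1 − κ)`.

The posterior is sampled with a block random-walk Metropolis–Hastings
sampler written for this model (logit/log proposal transforms, year-
checkerboard updates of the per-sample triples, Robbins–Monro step-size
adaptation during burn-in), with Gelman–Rubin convergence checks, shortest
(HPD) credible intervals, and a deviance-based posterior predictive check.
A forward simulator with the identical stochastic structure supports
parameter-recovery and calibration testing throughout.

## Worked example

`examples/01_simulate_and_fit.py` simulates a 3-site × 5-sample × 4-year
survey with shell persistence φ = 0.75 and refits it:

```
simulated 60 samples; mean unopened count I = 16.2
phi truth 0.75 -> posterior mean 0.747, 95% HPD [0.680, 0.819], R-hat 1.046

newly spun cocoons per sample at site 1 (posterior mean, 95% HPD):
  2009:  15.1 [  9.2,  21.3]  (truth 12)
  2010:  40.9 [ 29.9,  51.4]  (truth 47)
  2011:  41.6 [ 27.7,  54.7]  (truth 33)
  2012:   4.1 [  1.1,   8.5]  (truth 6)
```

The HPD interval brackets the generating φ, R-hat is near 1, and the
latent cocoon-rain estimates track the truth within their intervals. The
other examples show the total-rate algebra (`02`), the posterior
predictive check — moderate P-values on well-specified data, P ≈ 0 on
deliberately inflated counts (`03`) — and the validity analyses against
trap-capture and defoliation covariates (`04`).

A thin CLI wraps the same library calls:

```bash
cocoondyn simulate --seed 1 --out sim/
cocoondyn fit sim/counts.csv --preset desk --seed 2 --out fit/
cocoondyn ppc fit/samples.npz sim/counts.csv --seed 3 --out fit/
```

## Layout

```
src/cocoondyn/model.py     # types, cohort recursion, likelihood, priors
src/cocoondyn/mcmc.py      # block RW-MH sampler, R-hat, HPD, summaries
src/cocoondyn/_kernels.py  # numba inner loops (numpy reference retained)
src/cocoondyn/checks.py    # deviance PPC
src/cocoondyn/simulate.py  # forward simulator + default study design
src/cocoondyn/posthoc.py   # beta regression, correlations, summary table
src/cocoondyn/io.py        # CSV/YAML IO, packaged reference table
src/cocoondyn/cli.py       # simulate / fit / ppc / summary / posthoc
examples/                  # one narrative script per capability
```
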