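# Methods

## Model

The observation unit is one 0.04 m² soil core (sample *j*, site *i*, year
*t*) classified into unopened cocoons `I`, shells emptied by small-mammal
predation `M`, and shells emptied by anything else `H`. All three are
modelled as Poisson; the means come from a latent cohort recursion:

* `λI = N (1 − θ)` — of the `N` cocoons newly spun in year *t*, the
  fraction not yet preyed on by sampling time;
* `λM = N θ + φ (κ_prev I′ + M′)` — freshly preyed cocoons of the current
  generation, plus carried-over predated shells: last year's intact pool
  `I′` preyed on after sampling at rate `κ_prev`, plus the older predated
  pool `M′`, both decayed by the annual shell-remaining rate φ;
* `λH = φ ((1 − κ_prev) I′ + H′)` — the complementary part of `I′` that
  emerged (as adults or parasitoids) or died of disease, plus the older
  other-empty pool, likewise decayed.

The split of `I′` between the two empty categories uses weights
`κ_prev` and `1 − κ_prev`, so cohort accounting is exact: every intact
cocoon of year *t−1* is routed to exactly one destination.

Latent structure and priors:

* `N_ijt ~ Gamma(N_it/s, rate 1/s)` (mean `N_it`, variance `N_it·s`);
  `N_it` and `s` carry InvGamma(0.001, 0.001) hyperpriors.
* `θ_ijt ~ Beta(k_θ p_θ,it, k_θ(1−p_θ,it))`, `κ` analogously; the
  site-year means `p_θ, p_κ` are U(0, 1), the dispersions `k_θ, k_κ`
  Gamma(1, 1). (The hyperprior text sources conflict between Gamma(1, 1)
  and InvGamma(0.001, 0.001) for the `k`s; Gamma(1, 1) — the more specific
  statement — is the default and InvGamma is selectable via `PriorSpec`.)
* φ ~ U(0, 1).
* The pools `I′, M′, H′` feeding year *t* are latent with gamma priors
  moment-matched to the observed counts of year *t−1*, computed **per
  site-year across that year's J samples** (`shape = m²/v`, `rate = m/v`).
  Matching per site-year (rather than pooled) was chosen because the pools
  are site-year quantities and observed counts vary strongly by site and
  year. Degenerate cells are guarded by flooring the sample variance at
  0.25 and the mean at 0.1, keeping the matched gamma finite and weakly
  informative for empty cells.

### Open design points and how they were resolved

* **φ on freshly emptied shells.** Whether shells emptied *during* the
  year preceding sampling decay by φ before being counted is not decidable
  from the verbal model description. Default: φ multiplies every
  carried-over term (uniform treatment keeps φ interpretable as a single
  annual shell-survival rate). The alternative
  (`ProcessOptions(phi_on_fresh_empties=False)`) exempts the fresh terms
  `κ_prev I′` and `(1−κ_prev) I′`. Both variants share one code path in
  model, sampler and simulator.
* **First-year history.** Each site's first observed year has no preceding
  counts to moment-match, yet its `M` and `H` counts are usually nonzero.
  Default: free latent initial pools with vague Gamma(0.001, 0.001) priors
  plus a dummy prior-year rate `κ₀ ~ U(0, 1)` per sample.
  `ProcessOptions(zero_history=True)` instead pins the first-year pools at
  zero and floors `λM, λH` at 1e-6 to keep the likelihood proper.
* **ρ combination.** `ρ = 1 − (1−θ)(1−κ)` (complementary survival). The
  rule reproduces three published site-generation totals from their
  before/after components to the printed 3 decimals
  (`scripts/acceptance.py`, targets t1–t3).
* **Final-generation κ.** No following year constrains the last
  generation's after-sampling rate; it is still sampled (its posterior is
  prior-dominated) but `summarize_predation` reports NA for κ and ρ of the
  final generation.

## Sampler

Block random-walk Metropolis–Hastings on transformed coordinates (logit
for rates, log for positive quantities), with the transform Jacobian in
the acceptance ratio. Blocks per sweep, in fixed order:

1. per-sample triples `(N, θ, κ)` jointly per cell, on a checkerboard over
   years (even years, then odd): the triple at year *t* touches the
   likelihood at *t* (via N, θ) and at *t+1* (via κ), so simultaneous
   per-cell acceptance within one parity class is valid while neighbours
   are not — a unit test verifies that per-cell acceptance deltas sum
   exactly to the joint log-posterior change;
2. pools `(I′, M′, H′)` jointly per cell (plus `κ₀` at first-year cells);
3. `p_θ`, `p_κ`, `N_it` per site-year; φ, s, k_θ, k_κ singly.

Step sizes adapt by Robbins–Monro (gain `min(0.3, 2 n^−0.6)`) toward 0.23
acceptance for multivariate blocks and 0.44 for scalars, during burn-in
only; the post-burn-in kernel is fixed, so stationarity is untouched.
Initialization is overdispersed across chains: `N` and `N_it` start at
observed unopened counts + 1, rates uniform in moderate ranges, pools at
their prior means, vague-prior scales at unit order (draws from
InvGamma(0.001, 0.001) itself would be numerically absurd).

All chains advance in lock-step as a vectorized leading axis fed by one
seeded PCG64 stream, which also allows fitting many same-shaped replicate
datasets simultaneously (used by the simulation study in the test suite);
chains never interact, so each dataset receives a valid posterior sample.
The hot loops are compiled with numba; the pure-numpy implementation is
retained as the reference path, and a test drives both paths with an
identical random stream and requires the same trajectory.

Presets: `paper` = 3 chains × 5×10⁵ iterations, burn-in 2×10⁵, thin 100;
`desk` = 3 × 5×10⁴, burn-in 2×10⁴, thin 10 (9 000 retained draws), used
throughout the test suite so the full simulation study fits in minutes.

## Diagnostics and checks

* **Gelman–Rubin:** classical m-chain PSRF
  `sqrt(((n−1)/n · W + B/n)/W)`; 1.1 is reported as a convergence flag,
  never an error; zero within-chain variance returns NaN with a warning.
* **HPD:** Chen–Shao shortest interval over `ceil(0.95 n)` sorted draws,
  ties to the lowest window; never wider than the equal-tailed interval.
* **Posterior predictive check:** per category, each retained draw's
  Poisson means are held fixed, replicated counts are drawn at them, and
  the Bayesian P-value is the fraction of draws with replicated deviance ≥
  observed (ties count as ≥). Conditioning is on each draw's full latent
  state — the check replicates the observation layer only. A joint
  three-category P-value is available as supplementary output.

## Synthetic data

`simulate_dataset` draws per-sample `N`, θ, κ from the same distributions
the model assumes, propagates expected pools forward with the same
recursion (pools feeding year *t+1* are year *t*'s expected counts — the
simulator and the likelihood literally share `expected_counts_grid`, so
round-trip λ values are bit-identical), and observes Poisson counts.
`warmup_years` (default 2) generations are simulated and discarded so the
first observed year carries realistic shell history; the last warmup
year's κ becomes the true `κ₀`.

`default_study_design()` encodes the reference conditions: 8 sites × 10
samples × 4 years, φ = 0.75, site-year cocoon-rain means in the 4–60
per-sample range patterned on a real outbreak (most sites peak in year 2,
one site persistently dense), before-sampling predation means rising
0.05 → 0.40 over the outbreak with small site offsets, after-sampling
means 0.10–0.40, beta dispersions k = 10, gamma scale s = 2.

What the simulator does *not* emulate: spatial correlation between sites,
prolonged diapause (cocoons skipping a year), year-varying φ, and
overdispersion beyond the built-in gamma/beta mixing. Passing recovery
tests therefore show the machinery is correct and the design informative
— not that field data obey these assumptions.

## Simulation study sizes

The recovery and calibration tests use 20 replicate studies of the
default design fitted with the desk preset (all 20 stacked into one
60-chain sampler run). Observed results at these sizes: 95% HPD coverage
of φ = 0.75 in 20/20 replicates with mean posterior-mean bias ≈ +0.016,
and all per-category PPC P-values inside (0.05, 0.95). Twenty replicates
bound the binomial noise on a ≥90% criterion adequately while keeping the
study to a few minutes of CPU.

## Known limitations

* Years must form one contiguous global run; sites may start/stop within
  it and samples may be missing (mask), but gaps within a site's run are
  rejected because the carryover recursion needs consecutive years.
* φ is assumed constant over sites and years.
* The final generation's κ and ρ are unidentified (reported NA).
* Posterior means of φ show a small positive finite-sample bias at the
  default design (≈ +0.02), well inside the recovery tolerance.
* Beta regression requires responses strictly inside (0, 1); boundary
  values are shrunk by the standard `(y(n−1)+0.5)/n` correction.
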