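"""Validate predation estimates against independent field covariates.

Two biological sanity checks: estimated predation rates should rise with
small-mammal abundance (trap-capture index, via beta regression), and the
estimated number of newly spun cocoons should track defoliation intensity
(via Pearson correlation).  Here both covariates are synthesized so that
the expected relationships hold, demonstrating the analysis pipeline.
"""

import numpy as np
import pandas as pd

import cocoondyn as cd
from cocoondyn.mcmc import ChainConfig
from cocoondyn.posthoc import (correlate_abundance_with_defoliation,
                               regress_predation_on_captures,
                               summarize_predation)

truth = cd.default_study_design(seed=5)
sim = cd.simulate_dataset(truth)
config = ChainConfig.desk(seed=6, n_iterations=15_000, burn_in=6_000, thin=10)
post = cd.run_chains(sim.counts, config=config)
summary = summarize_predation(post)

# synthetic trap captures: predator abundance follows the generating
# predation pressure, so the regressions should find positive slopes
rng = np.random.default_rng(7)
rows = []
for t, year in enumerate(sim.counts.years):
    autumn = 40 * truth.p_theta[:, t].mean() + rng.normal(0, 0.5)
    rows += [(s, int(year), "autumn", max(autumn + rng.normal(0, 0.5), 0))
             for s in ("LP", "HP", "LN", "HN")]
    spring = 40 * truth.p_kappa[:, t].mean() + rng.normal(0, 0.5)
    rows += [(s, int(year) + 1, "spring", max(spring + rng.normal(0, 0.5), 0))
             for s in ("LP", "HP", "LN", "HN")]
traps = pd.DataFrame(rows, columns=["site", "year", "season", "captures"])

print("beta regression of predation rates on trap captures:")
print(regress_predation_on_captures(summary, traps).to_string(index=False))

# synthetic defoliation: proportional to cocoon rain plus noise
defol = pd.DataFrame(
    [(site, int(year),
      float(np.clip(1.2 * truth.N_mean[i, t] + rng.normal(0, 6), 0, 100)))
     for i, site in enumerate(sim.counts.sites)
     for t, year in enumerate(sim.counts.years)],
    columns=["site", "year", "intensity"])

print("\nPearson correlation of abundance with defoliation intensity:")
print(correlate_abundance_with_defoliation(
    summary, sim.counts, defol).to_string(index=False))
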