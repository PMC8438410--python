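"""What the population simulator generates, and how to check it.

Subpopulation allele frequencies follow the Balding-Nichols F-model
around ancestral Dirichlet draws; inbreeding enters as autozygosity
(probability Fis of duplicating a single allele draw).  The inbreeding
coefficient is recoverable from the simulated data as 1 - Ho/He.
"""

import numpy as np

from ssrcore import SimulationConfig, locus_stats_table, simulate

config = SimulationConfig(
    n_accessions=1000,
    locus_allele_counts=(4,) * 14 + (3,) * 14,
    k_subpops=1,
    fis=0.3,
    missing_rate=0.05,
    dirichlet_concentration=0.8,
)
matrix, truth = simulate(config, seed=5)

stats = locus_stats_table(matrix, mean_row=False)
f_hat = 1.0 - stats["Ho"] / stats["He"]
se = f_hat.std(ddof=1) / np.sqrt(len(f_hat))
print(f"target Fis     : {config.fis}")
print(f"realised Fis   : {truth.realized_fis:.4f} (fraction of autozygous draws)")
print(f"estimated Fis  : {f_hat.mean():.4f} +/- {se:.4f} (across {len(f_hat)} loci)")
print(f"missing rate   : {matrix.missing_mask().mean():.4f} (target {config.missing_rate})")

print(
    "\nThe estimate 1 - Ho/He averaged over loci recovers the inbreeding "
    "coefficient within Monte-Carlo error; that check is what licenses "
    "using the simulator as a stand-in population for pipeline tests."
)
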