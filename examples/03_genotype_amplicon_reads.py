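"""Allele-ratio genotyping of simulated amplicon FASTQ files.

Simulates a 2-population study at tissue-grade depth, writes one FASTQ
per individual, genotypes them by counting allele-specific probe hits,
and checks the calls against the simulation truth.
"""

import tempfile
from pathlib import Path

from gtpanel.concordance import compare_matrices
from gtpanel.genotyper import genotype_fastq_dir, genotyping_success
from gtpanel.simdata import SimConfig, simulate_study

cfg = SimConfig(n_pops=2, n_individuals_per_pop=8, n_loci=50,
                depth_model=("poisson", 100.0), error_rate=0.001, seed=42)

with tempfile.TemporaryDirectory() as tmp:
    loci, truth, reads, tallies = simulate_study(cfg, out_dir=tmp)
    fastqs = {p.stem: p for p in Path(tmp).glob("*.fastq")}
    called, counts = genotype_fastq_dir(fastqs, loci, meta=truth.meta)

pct, summary = genotyping_success(called)
print(f"individuals: {called.n_individuals}, loci: {called.n_loci}")
print(f"mean % loci genotyped: {pct.mean():.2f}")
report = compare_matrices(truth, called)
print(f"discordance vs truth: {report.discordance_rate:.4f} "
      f"({report.mean_discordant:.2f} of {report.mean_both_called:.2f} loci/individual)")
# At ~100x depth the ratio caller recovers essentially every genotype;
# residual missingness comes from dead-zone ratios and <10-read cells.
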