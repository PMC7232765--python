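"""Generate a complete synthetic input bundle.

Writes genotypes (VCF + TSV), per-individual CpG coverage files, a GFF3
gene annotation, a population map and a daily salinity series into
./example_inputs, using the default four-population estuarine design.
"""

import numpy as np

from epifst import (SimConfig, population_map, simulate_genome_annotation,
                    simulate_genotypes, simulate_methylomes,
                    simulate_salinity_series)

cfg = SimConfig(n_loci=400, n_tiles=300, n_genes=15, genome_length=150_000,
                n_individuals_per_pop=12, seed=1)
outdir = "example_inputs"

matrix, popmap = simulate_genotypes(cfg, outdir=outdir)
sim = simulate_methylomes(cfg, outdir=outdir)
simulate_genome_annotation(cfg, path=f"{outdir}/genes.gff3")
sites = list(popmap["site"].unique())
sal = simulate_salinity_series(dict(zip(sites, np.linspace(22, 4, 4))),
                               noise_sd=4.0, n_days=365, seed=cfg.seed,
                               outdir=outdir)
sal.to_csv(f"{outdir}/salinity.csv", index=False)

print(f"wrote {matrix.n_loci} loci x {matrix.n_individuals} individuals, "
      f"{cfg.n_tiles} tiles x {len(sim.coverages)} coverage files, "
      f"{cfg.n_genes} genes, {len(sal)} salinity days -> {outdir}/")
print("every file is in a standard format (VCF, bismark coverage TSV, "
      "GFF3, CSV) that the analysis modules read back directly")
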