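"""Tile methylomes and call differentially methylated regions.

Simulates CpG coverage for two meta-populations, filters CpGs to >= 10
reads, pools counts into 100-bp tiles occupied by >= 8 individuals per
group, and tests each tile (binomial logistic LRT, BH adjustment,
|difference| >= 15 points and q <= 0.05).
"""

from epifst import (SimConfig, dmr_test, filter_by_coverage, make_tiles,
                    simulate_methylomes)

cfg = SimConfig(n_populations=2, n_individuals_per_pop=10, n_tiles=500,
                sigma_between=0.06, base_mean_range=(0.4, 0.6),
                genome_length=50_000, seed=2)
sim = simulate_methylomes(cfg)
covs = {i: filter_by_coverage(c, min_reads=10)
        for i, c in sim.coverages.items()}
groups = dict(zip(sim.popmap["individual"], sim.popmap["site"]))
tiles = make_tiles(covs, groups, tile=100, step=100,
                   min_individuals_per_group=8)
g1, g2 = sorted(set(groups.values()))
result = dmr_test(tiles, g1, g2)

n_hyper = (result["call"] == "hyper").sum()
n_hypo = (result["call"] == "hypo").sum()
print(f"{tiles.n_tiles} tiles pass the occupancy rule")
print(f"{n_hyper} hyper- and {n_hypo} hypomethylated DMRs in {g1} vs {g2}")
print(result.loc[result['call'] != 'ns',
                 ['tile', 'meth_diff', 'q', 'call']].head().to_string())
print("a DMR needs both a >= 15-point pooled percentage difference and "
      "q <= 0.05, so deep coverage alone can never create one")
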