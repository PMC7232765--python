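"""Synthetic genotype, methylome, annotation and salinity generators.

The generators emit the same standard formats the analysis reads (VCF,
genotype TSV, bismark-style coverage TSV, GFF3, salinity CSV) with the
statistical structure the pipeline assumes:

* genotypes follow a Balding–Nichols model — per-population allele
  frequencies are Beta-distributed around a uniform ancestral frequency
  with a single divergence parameter F that equals the expected
  Weir–Cockerham theta;
* per-individual tile methylation fractions follow a hierarchical Gaussian
  model (tile baseline + population offset + individual noise, truncated
  to [0, 1]) with per-CpG Poisson read depths and binomial methylated
  counts on top;
* gene models are non-overlapping genes on both strands with UTRs, exons
  and derived introns;
* salinity series are Gaussian noise around a site mean, floored at 0 psu.

Everything is driven by one :class:`~epifst.config.SimConfig`; a fixed seed
gives byte-identical output files.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig
from .fst import GenotypeMatrix
from .tiles import CpGCoverage, write_coverage

__all__ = [
    "simulate_genotypes",
    "simulate_methylomes",
    "simulate_tile_fractions",
    "simulate_genome_annotation",
    "simulate_salinity_series",
    "SimMethylomes",
    "population_map",
    "write_vcf",
]

# Site codes of a four-estuary design and their two meta-populations
# (high/low salinity clusters); generic names are used for other counts.
_SITE_CODES = ["LC", "LF", "SL", "VB"]
_META_OF = {"LC": "meta1", "SL": "meta1", "LF": "meta2", "VB": "meta2"}


def population_map(config: SimConfig) -> pd.DataFrame:
    """Individual -> site -> meta-population table for a config.

    For four populations the site codes are LC/LF/SL/VB with the K=2
    meta-population grouping (LC+SL vs LF+VB); otherwise sites are P1..Pk
    split half-and-half into two meta-populations.
    """
    k, n = config.n_populations, config.n_individuals_per_pop
    if k == 4:
        sites = _SITE_CODES
        meta = _META_OF
    else:
        sites = [f"P{i + 1}" for i in range(k)]
        meta = {s: ("meta1" if i < k / 2 else "meta2")
                for i, s in enumerate(sites)}
    rows = [{"individual": f"{s}_{j + 1:02d}", "site": s,
             "meta_population": meta[s]}
            for s in sites for j in range(n)]
    return pd.DataFrame(rows)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Independent generator per logical stream, all rooted in config.seed."""
    key = zlib.crc32(stream.encode()) % 2**31
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(config: SimConfig, outdir: Optional[Path] = None,
                       ) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Balding–Nichols genotypes for k populations of n diploids.

    Per locus the ancestral frequency p is uniform on
    ``config.ancestral_freq_range``; each population's frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``config.divergence_F``;
    genotypes are Binomial(2, p_pop) ALT dosages, masked missing at
    ``config.missing_rate``.  When ``outdir`` is given, writes
    ``genotypes.vcf``, ``genotypes.tsv`` and ``popmap.tsv``.
    """
    popmap = population_map(config)
    rng = _rng(config, "genotypes")
    k, L = config.n_populations, config.n_loci
    n = config.n_individuals_per_pop
    F = config.divergence_F

    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=L)
    ratio = (1.0 - F) / F
    p_pop = rng.beta(p_anc[:, None] * ratio, (1.0 - p_anc[:, None]) * ratio,
                     size=(L, k))
    calls = rng.binomial(2, np.repeat(p_pop, n, axis=1)).astype(float)
    if config.missing_rate > 0:
        calls[rng.random(calls.shape) < config.missing_rate] = np.nan

    pos = np.sort(rng.choice(config.genome_length, size=L, replace=False))
    loci = pd.DataFrame({
        "chrom": "chr1",
        "pos": pos,
        "rad_id": [f"RAD{i + 1:06d}" for i in range(L)],
    })
    matrix = GenotypeMatrix(loci, list(popmap["individual"]),
                            popmap["site"].to_numpy(), calls)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(matrix, outdir / "genotypes.vcf",
                  contig_length=config.genome_length)
        matrix.to_tsv(outdir / "genotypes.tsv")
        popmap.to_csv(outdir / "popmap.tsv", sep="\t", index=False)
    return matrix, popmap


def write_vcf(matrix: GenotypeMatrix, path, contig_length: Optional[int] = None
              ) -> None:
    """Write a minimal VCF 4.2 with GT fields from a dosage matrix."""
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=epifst-simulate\n")
        for chrom in pd.unique(matrix.loci["chrom"]):
            if contig_length is not None:
                fh.write(f"##contig=<ID={chrom},length={contig_length}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.individuals) + "\n")
        for i, locus in enumerate(matrix.loci.itertuples()):
            cells = [gt.get(v, "./.") for v in matrix.calls[i]]
            fh.write(f"{locus.chrom}\t{locus.pos + 1}\t{locus.rad_id}\tA\tG\t"
                     f".\tPASS\t.\tGT\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# methylomes

@dataclass
class SimMethylomes:
    """Simulated methylome bundle.

    ``true_fractions`` is the (n_tiles, n_individuals) matrix of latent
    per-individual tile methylation fractions before read sampling —
    useful for calibration checks; ``coverages`` holds the per-individual
    CpG read counts the pipeline actually consumes.
    """

    coverages: Dict[str, CpGCoverage]
    popmap: pd.DataFrame
    true_fractions: np.ndarray
    tile_starts: np.ndarray
    chrom: str = "chr1"


def simulate_tile_fractions(config: SimConfig,
                            rng: Optional[np.random.Generator] = None
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Latent per-individual methylation fractions of the hierarchical model.

    Per tile: baseline mu ~ Uniform(base_mean_range); population offset
    ~ Normal(0, sigma_between); individual fraction ~ Normal(pop mean,
    sigma_within) truncated to [0, 1].  Returns (fractions with shape
    (n_tiles, k*n), population labels per column).  Warns when the
    truncation mass at any tile exceeds 10% (variance distortion).
    """
    if rng is None:
        rng = _rng(config, "methylomes")
    k, n, T = config.n_populations, config.n_individuals_per_pop, config.n_tiles
    mu = rng.uniform(*config.base_mean_range, size=T)
    pop_mean = mu[:, None] + rng.normal(0.0, config.sigma_between, size=(T, k))
    ind_mean = np.repeat(pop_mean, n, axis=1)
    frac = rng.normal(ind_mean, config.sigma_within)
    if config.sigma_within > 0:
        z_lo = (0.0 - ind_mean) / config.sigma_within
        z_hi = (1.0 - ind_mean) / config.sigma_within
        mass_out = stats.norm.cdf(z_lo) + stats.norm.sf(z_hi)
        worst = float(mass_out.max())
        if worst > 0.10:
            warnings.warn(
                f"truncation mass {worst:.1%} exceeds 10% at some tile; "
                "within-population variance will be distorted",
                stacklevel=2)
    np.clip(frac, 0.0, 1.0, out=frac)
    labels = np.repeat([f"pop{j}" for j in range(k)], n)
    return frac, labels


def simulate_methylomes(config: SimConfig, outdir: Optional[Path] = None
                        ) -> SimMethylomes:
    """Per-individual bismark-style CpG coverage over 100-bp tiles.

    Tiles occupy consecutive ``tile_size`` windows from coordinate 0 with
    ``cpgs_per_tile`` CpG sites each; per CpG the read depth is
    Poisson(mean_read_depth) and the methylated count Binomial(depth,
    individual tile fraction).  CpGs with zero depth are not emitted
    (uncovered sites are absent from real coverage files).  When ``outdir``
    is given, writes one ``<individual>.cov`` per individual (zero-based
    dialect) plus ``popmap.tsv``.
    """
    rng = _rng(config, "methylomes")
    popmap = population_map(config)
    frac, _ = simulate_tile_fractions(config, rng)
    T, N = frac.shape
    C = config.cpgs_per_tile
    tile_starts = np.arange(T) * config.tile_size

    # C distinct CpG offsets within each tile, sorted for coordinate order
    offsets = np.empty((T, C), dtype=int)
    for t in range(T):
        offsets[t] = np.sort(rng.choice(config.tile_size, size=C, replace=False))
    cpg_pos = (tile_starts[:, None] + offsets).ravel()

    depth = rng.poisson(config.mean_read_depth, size=(T * C, N))
    meth = rng.binomial(depth, np.repeat(frac, C, axis=0))

    coverages: Dict[str, CpGCoverage] = {}
    for j, ind in enumerate(popmap["individual"]):
        covered = depth[:, j] > 0
        rec = pd.DataFrame({
            "chrom": "chr1",
            "pos": cpg_pos[covered],
            "meth": meth[covered, j],
            "unmeth": depth[covered, j] - meth[covered, j],
        })
        coverages[ind] = CpGCoverage(ind, rec)

    sim = SimMethylomes(coverages, popmap, frac, tile_starts)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for ind, cov in coverages.items():
            write_coverage(cov, outdir / f"{ind}.cov", dialect="zero_based")
        popmap.to_csv(outdir / "popmap.tsv", sep="\t", index=False)
    return sim


# ---------------------------------------------------------------------------
# genome annotation

def simulate_genome_annotation(config: SimConfig, path: Optional[Path] = None
                               ) -> str:
    """Non-overlapping gene models as GFF3 text (optionally written to path).

    Genes alternate strands and carry a 5'UTR, 1–4 exons with derived
    introns, and a 3'UTR; 2-kb flanks are left free so promoter/downstream
    windows of neighbouring genes rarely collide.  Raises when the packing
    does not fit in ``genome_length``.
    """
    rng = _rng(config, "annotation")
    G = config.n_genes
    lines = ["##gff-version 3",
             f"##sequence-region chr1 1 {config.genome_length}"]
    if G > 0:
        spans = []
        for _ in range(G):
            n_exons = int(rng.integers(1, 5))
            exon_lens = rng.integers(80, 301, size=n_exons)
            intron_lens = rng.integers(100, 501, size=max(n_exons - 1, 0))
            spans.append((exon_lens, intron_lens,
                          int(exon_lens.sum() + intron_lens.sum())))
        total = sum(s[2] for s in spans)
        gap = 4200  # promoter + downstream flank with margin
        need = total + gap * (G + 1)
        if need > config.genome_length:
            raise ValueError(
                f"cannot pack {G} genes ({need} bp needed) into "
                f"{config.genome_length} bp")
        slack = config.genome_length - need
        extra = rng.multinomial(slack, np.full(G + 1, 1.0 / (G + 1)))
        cursor = gap + int(extra[0])
        for gi, (exon_lens, intron_lens, span) in enumerate(spans):
            start = cursor                      # 0-based
            end = start + span
            strand = "+" if gi % 2 == 0 else "-"
            gid = f"gene{gi + 1:04d}"
            # exon intervals within [start, end)
            exons = []
            pos = start
            for ei, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el)))
                if ei < len(intron_lens):
                    pos += int(el) + int(intron_lens[ei])
                else:
                    pos += int(el)
            u5 = int(rng.integers(40, min(120, exon_lens[0 if strand == "+" else -1])))
            u3 = int(rng.integers(40, min(120, exon_lens[-1 if strand == "+" else 0])))
            if strand == "+":
                utr5 = (exons[0][0], exons[0][0] + u5)
                utr3 = (exons[-1][1] - u3, exons[-1][1])
            else:
                utr5 = (exons[-1][1] - u5, exons[-1][1])
                utr3 = (exons[0][0], exons[0][0] + u3)

            def row(ftype, s, e, attrs):
                # GFF3 is 1-based inclusive
                return (f"chr1\tepifst\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t."
                        f"\t{attrs}")

            lines.append(row("gene", start, end, f"ID={gid}"))
            lines.append(row("mRNA", start, end,
                             f"ID={gid}.t1;Parent={gid}"))
            for ei, (es, ee) in enumerate(exons):
                lines.append(row("exon", es, ee,
                                 f"ID={gid}.e{ei + 1};Parent={gid}.t1"))
            lines.append(row("five_prime_UTR", utr5[0], utr5[1],
                             f"ID={gid}.u5;Parent={gid}.t1"))
            lines.append(row("three_prime_UTR", utr3[0], utr3[1],
                             f"ID={gid}.u3;Parent={gid}.t1"))
            cursor = end + gap + int(extra[gi + 1])
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# salinity

def simulate_salinity_series(site_means: Mapping[str, float],
                             noise_sd: float, n_days: int, seed: int,
                             start_date: str = "2015-01-01",
                             outdir: Optional[Path] = None) -> pd.DataFrame:
    """Daily salinity per site: site mean + Gaussian noise, floored at 0 psu.

    Returns a long table (site, date, psu); when ``outdir`` is given also
    writes one ``salinity_<site>.csv`` per site.
    """
    if n_days < 10:
        raise ValueError("n_days must be >= 10")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    frames = []
    for site, mean in site_means.items():
        psu = np.maximum(rng.normal(mean, noise_sd, size=n_days), 0.0)
        frames.append(pd.DataFrame({
            "site": site,
            "date": dates.strftime("%Y-%m-%d"),
            "psu": np.round(psu, 4),
        }))
    out = pd.concat(frames, ignore_index=True)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for site, sub in out.groupby("site", sort=False):
            sub.to_csv(outdir / f"salinity_{site}.csv", index=False)
    return out
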