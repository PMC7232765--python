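"""Simulation configuration.

:class:`SimConfig` collects every knob of the synthetic-data generators in
one validated, immutable record.  The defaults describe the sampling design
the package targets: four estuarine populations of ~20 diploid individuals,
~1,500 low-divergence biallelic RAD loci, and 100-bp CpG tiles whose
methylation fractions follow a hierarchical (between-population /
within-population) Gaussian model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

__all__ = ["SimConfig"]


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic genotype/methylome/annotation generators.

    Attributes
    ----------
    n_populations, n_individuals_per_pop, n_loci
        Sampling design of the genotype simulation.
    divergence_F
        Balding–Nichols divergence parameter; equals the expected
        Weir–Cockerham theta of the simulated loci.  Must be strictly
        inside (0, 1): the Beta distribution degenerates at the ends.
    ancestral_freq_range
        Range of the uniform ancestral allele-frequency draw.
    missing_rate
        Per-call probability that a genotype is masked missing.
    n_tiles, cpgs_per_tile, mean_read_depth
        Methylome layout: number of 100-bp tiles, CpGs simulated per tile,
        Poisson mean of the per-CpG read depth.
    sigma_between, sigma_within
        Standard deviations (on the methylation-fraction scale) of the
        population offsets and of individuals around their population mean.
    base_mean_range
        Range of the per-tile baseline methylation fraction; kept away from
        0/1 so truncation of the Gaussian noise is negligible.
    genome_length, n_genes
        Synthetic genome size (bp, single chromosome) and gene count for
        the GFF3 annotation generator.
    seed
        Root seed; a fixed seed makes every generator byte-reproducible.
    """

    n_populations: int = 4
    n_individuals_per_pop: int = 20
    n_loci: int = 1567
    divergence_F: float = 1.0 / 43.5
    ancestral_freq_range: Tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.1
    n_tiles: int = 1000
    sigma_between: float = 0.0383
    sigma_within: float = 0.10
    base_mean_range: Tuple[float, float] = (0.3, 0.7)
    mean_read_depth: float = 30.0
    cpgs_per_tile: int = 5
    genome_length: int = 500_000
    n_genes: int = 40
    seed: int = 0
    tile_size: int = field(default=100, repr=False)

    def __post_init__(self) -> None:
        for name in ("n_populations", "n_individuals_per_pop", "n_loci",
                     "n_tiles", "cpgs_per_tile", "genome_length", "tile_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_populations < 2:
            raise ValueError("need at least two populations")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if not (0.0 < self.divergence_F < 1.0):
            raise ValueError(
                "divergence_F must lie strictly in (0, 1); the Balding-Nichols "
                f"Beta distribution is degenerate at F={self.divergence_F!r}")
        _check_fraction("missing_rate", self.missing_rate)
        for lo, hi, name in (
            (*self.ancestral_freq_range, "ancestral_freq_range"),
            (*self.base_mean_range, "base_mean_range"),
        ):
            _check_fraction(name, lo)
            _check_fraction(name, hi)
            if lo > hi:
                raise ValueError(f"{name} must be (low, high), got ({lo}, {hi})")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValueError("sigma values must be non-negative")
        if self.mean_read_depth < 1:
            raise ValueError("mean_read_depth must be >= 1")
        if self.n_tiles * self.tile_size > self.genome_length:
            raise ValueError(
                f"{self.n_tiles} tiles of {self.tile_size} bp do not fit in a "
                f"genome of {self.genome_length} bp")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
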