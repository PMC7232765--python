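"""Per-locus, mean, and gene-level Weir & Cockerham F_ST.

The estimator is the Weir & Cockerham (1984) method-of-moments theta built
from three variance components per biallelic locus: ``a`` (among
populations), ``b`` (among individuals within populations) and ``c``
(within individuals), with ``theta = a / (a + b + c)``.  Loci are filtered
the way RAD-seq population pipelines do: per-population call-rate,
genome-wide minor allele frequency, and one SNP per RAD locus.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "FstLocus",
    "wc_theta",
    "fst_per_locus",
    "filter_loci",
    "mean_fst",
    "gene_weighted_fst",
    "read_genotype_tsv",
    "read_vcf",
]


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with locus metadata and population labels.

    ``calls`` is float-typed, shape (n_loci, n_individuals), holding the
    ALT-allele dosage 0/1/2 or NaN for missing.  ``loci`` carries one row
    per locus with columns ``chrom``, ``pos`` (0-based bp) and ``rad_id``.
    """

    loci: pd.DataFrame
    individuals: list
    populations: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.loci), len(self.individuals)):
            raise ValueError("calls shape does not match loci x individuals")
        if len(self.populations) != len(self.individuals):
            raise ValueError("one population label per individual required")
        if (self.loci["pos"] < 0).any():
            raise ValueError("locus positions must be non-negative")
        if len(pd.unique(self.populations)) < 2:
            raise ValueError("at least two populations required")
        with np.errstate(invalid="ignore"):
            bad = ~np.isin(self.calls[~np.isnan(self.calls)], (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError("genotype calls must be 0, 1, 2 or missing")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def pop_names(self) -> list:
        return list(pd.unique(self.populations))

    def to_tsv(self, path) -> None:
        """Write the matrix as loci-by-individuals TSV with 0/1/2/NA codes."""
        df = pd.DataFrame(self.calls, columns=self.individuals)
        df.insert(0, "chrom", self.loci["chrom"].values)
        df.insert(1, "pos", self.loci["pos"].values)
        df.insert(2, "rad_id", self.loci["rad_id"].values)
        out = df.copy()
        for c in self.individuals:
            out[c] = out[c].map(lambda v: "NA" if np.isnan(v) else str(int(v)))
        out.to_csv(path, sep="\t", index=False)


@dataclass
class FstLocus:
    """WC84 summary for one locus: per-population inputs and components."""

    locus_id: str
    n: np.ndarray          # diploid sample size per population
    p: np.ndarray          # ALT allele frequency per population
    h: np.ndarray          # observed heterozygote proportion per population
    a: float
    b: float
    c: float
    theta: float           # NaN when a + b + c == 0 (monomorphic)


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised WC84 variance components.

    Inputs are (L, r) arrays; populations absent at a locus carry n == 0 and
    are excluded from that locus's terms.  Returns (a, b, c), each length L,
    NaN where fewer than two populations are informative or nbar <= 1.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    if n.ndim == 1:
        n, p, h = n[None, :], p[None, :], h[None, :]
    if (np.nan_to_num(p) < 0).any() or (np.nan_to_num(p) > 1).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    valid = n > 0
    r = valid.sum(axis=1).astype(float)
    p = np.where(valid, p, 0.0)
    h = np.where(valid, h, 0.0)
    n_tot = n.sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n_tot / r
        nc = (n_tot - (n ** 2).sum(axis=1) / n_tot) / (r - 1.0)
        pbar = (n * p).sum(axis=1) / n_tot
        s2 = (n * (p - pbar[:, None]) ** 2 * valid).sum(axis=1) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=1) / n_tot

        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (pbar * (1 - pbar)
                                   - (r - 1.0) / r * s2
                                   - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0

    bad = (r < 2) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_theta(n: Sequence[float], p: Sequence[float], h: Sequence[float],
             locus_id: str = "locus") -> FstLocus:
    """WC84 theta for one locus from per-population (n_i, p_i, h_i).

    Parameters
    ----------
    n, p, h
        Per-population diploid sample sizes, ALT allele frequencies and
        observed heterozygote proportions.  At least two populations with
        n_i >= 1 are required.

    Returns
    -------
    FstLocus with components a, b, c and ``theta = a/(a+b+c)``; theta is NaN
    for a globally monomorphic locus (zero denominator).
    """
    n = np.asarray(n, dtype=float)
    if (n > 0).sum() < 2:
        raise ValueError("wc_theta requires >= 2 populations with n_i >= 1")
    a, b, c = _wc_components(n, np.asarray(p, float), np.asarray(h, float))
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    denom = a + b + c
    theta = a / denom if denom != 0 and np.isfinite(denom) else float("nan")
    return FstLocus(locus_id, n, np.asarray(p, float), np.asarray(h, float),
                    a, b, c, theta)


def _pop_summaries(matrix: GenotypeMatrix):
    """Per-locus per-population (n_i, p_i, h_i) from the dosage matrix."""
    pops = matrix.pop_names
    L = matrix.n_loci
    n = np.zeros((L, len(pops)))
    p = np.zeros((L, len(pops)))
    h = np.zeros((L, len(pops)))
    for j, pop in enumerate(pops):
        sub = matrix.calls[:, matrix.populations == pop]
        called = ~np.isnan(sub)
        n_j = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[:, j] = np.nansum(sub, axis=1) / (2.0 * n_j)
            h[:, j] = (sub == 1.0).sum(axis=1) / n_j
        n[:, j] = n_j
    p[n == 0] = 0.0
    h[n == 0] = 0.0
    return pops, n, p, h


def fst_per_locus(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus WC84 components and theta for every locus in the matrix.

    Returns a DataFrame with locus metadata plus columns a, b, c, theta;
    theta is NaN where undefined (monomorphic or < 2 informative
    populations).
    """
    _, n, p, h = _pop_summaries(matrix)
    a, b, c = _wc_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    out = matrix.loci.copy()
    out["a"], out["b"], out["c"], out["theta"] = a, b, c, theta
    return out


def filter_loci(matrix: GenotypeMatrix,
                min_presence: float = 0.65,
                min_pops_passing: int = 2,
                min_maf: float = 0.05,
                one_snp_per_radlocus: bool = True) -> GenotypeMatrix:
    """RAD-style locus filters.

    Keeps loci that are genotyped in at least ``min_presence`` of the
    individuals of at least ``min_pops_passing`` populations, have overall
    minor-allele frequency >= ``min_maf`` among called alleles, and (when
    ``one_snp_per_radlocus``) are the first surviving SNP of their RAD
    locus.  Idempotent; may return an empty matrix.
    """
    called = ~np.isnan(matrix.calls)
    pops = matrix.pop_names
    pass_pops = np.zeros(matrix.n_loci, dtype=int)
    for pop in pops:
        mask = matrix.populations == pop
        frac = called[:, mask].sum(axis=1) / mask.sum()
        pass_pops += (frac >= min_presence).astype(int)
    keep = pass_pops >= min_pops_passing

    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.nansum(matrix.calls, axis=1) / (2.0 * n_called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep &= np.where(n_called > 0, maf >= min_maf, False)

    if one_snp_per_radlocus:
        order = np.lexsort((matrix.loci["pos"].values,
                            matrix.loci["rad_id"].values))
        seen = set()
        first = np.zeros(matrix.n_loci, dtype=bool)
        for idx in order:
            if not keep[idx]:
                continue
            rid = matrix.loci["rad_id"].values[idx]
            if rid not in seen:
                seen.add(rid)
                first[idx] = True
        keep &= first

    return GenotypeMatrix(matrix.loci.loc[keep].reset_index(drop=True),
                          matrix.individuals, matrix.populations,
                          matrix.calls[keep])


def mean_fst(fst_table: pd.DataFrame) -> Tuple[float, float]:
    """Genome-wide F_ST summaries over loci with defined theta.

    Returns ``(mean_of_thetas, ratio_of_sums)`` where the first is the
    arithmetic mean of per-locus theta (the headline statistic) and the
    second is sum(a)/sum(a+b+c) over the same loci.
    """
    ok = fst_table["theta"].notna()
    if not ok.any():
        raise ValueError("no locus with defined theta")
    sub = fst_table.loc[ok]
    mean_of_thetas = float(sub["theta"].mean())
    denom = float((sub["a"] + sub["b"] + sub["c"]).sum())
    ratio_of_sums = float(sub["a"].sum() / denom)
    return mean_of_thetas, ratio_of_sums


def gene_weighted_fst(fst_table: pd.DataFrame, genes: pd.DataFrame,
                      flank: int = 2000) -> pd.DataFrame:
    """Weighted gene-body F_ST: sum(a)/sum(a+b+c) over loci in each body.

    ``genes`` needs columns gene_id, chrom, start, end (0-based half-open);
    a :class:`~epifst.annotation.FeatureModel` is accepted too.  The gene
    body spans ``flank`` bp upstream through ``flank`` bp downstream.  A
    locus inside two overlapping bodies counts in both; genes with no locus
    are absent from the output.
    """
    genes = getattr(genes, "genes", genes)
    rows = []
    ok = fst_table["theta"].notna()
    tab = fst_table.loc[ok]
    for chrom, gsub in genes.groupby("chrom", sort=False):
        lsub = tab[tab["chrom"] == chrom].sort_values("pos")
        if lsub.empty:
            continue
        pos = lsub["pos"].values
        for g in gsub.itertuples():
            lo = max(0, g.start - flank)
            hi = g.end + flank
            i, j = np.searchsorted(pos, [lo, hi])
            if i == j:
                continue
            sel = lsub.iloc[i:j]
            denom = float((sel["a"] + sel["b"] + sel["c"]).sum())
            rows.append({
                "gene_id": g.gene_id, "chrom": chrom, "n_loci": j - i,
                "fst": float(sel["a"].sum() / denom) if denom != 0 else np.nan,
            })
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "n_loci", "fst"])


def read_genotype_tsv(path, popmap: pd.DataFrame) -> GenotypeMatrix:
    """Read a loci-by-individuals 0/1/2/NA genotype TSV.

    ``popmap`` maps individuals to populations (columns ``individual`` and
    ``population`` — or ``site``/``meta_population``, selected by the
    caller renaming to ``population``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = df[["chrom", "pos", "rad_id"]].copy()
    inds = [c for c in df.columns if c not in ("chrom", "pos", "rad_id")]
    calls = (df[inds].replace("NA", np.nan).astype(float)).to_numpy()
    pops = _lookup_pops(popmap, inds)
    return GenotypeMatrix(meta, inds, pops, calls)


def _lookup_pops(popmap: pd.DataFrame, individuals) -> np.ndarray:
    pm = popmap.set_index("individual")
    col = "population" if "population" in pm.columns else "site"
    missing = [i for i in individuals if i not in pm.index]
    if missing:
        raise ValueError(f"individuals absent from population map: {missing[:5]}")
    return pm.loc[individuals, col].to_numpy()


def read_vcf(path, popmap: pd.DataFrame) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    The RAD locus id is taken from the ID column (falling back to
    chrom:pos).  Positions are converted to 0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    inds = list(vcf.samples)
    pops = _lookup_pops(popmap, inds)
    rows, calls = [], []
    code = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}  # cyvcf2 gt_types
    for v in vcf:
        rows.append({"chrom": v.CHROM, "pos": v.POS - 1,
                     "rad_id": v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"})
        calls.append([code[t] for t in v.gt_types])
    vcf.close()
    meta = pd.DataFrame(rows, columns=["chrom", "pos", "rad_id"])
    return GenotypeMatrix(meta, inds, pops,
                          np.asarray(calls, dtype=float).reshape(len(meta), len(inds)))
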