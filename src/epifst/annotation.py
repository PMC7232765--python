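"""Genomic feature model, tile classification and random-tile nulls.

From a GFF3 the module derives, per gene: promoter (2 kb upstream,
strand-aware), 5'UTR, exons, introns (gene span minus exons), 3'UTR and a
2-kb strand-aware downstream window.  Tiles are labelled with the category
of maximal overlap (ties broken by a fixed precedence), or intergenic with
a nearest gene when they overlap no gene-linked category.  Random tile
sets drawn uniformly over the genome provide the null feature
distribution, and two category distributions are compared with a
two-sample Kolmogorov–Smirnov test on their fraction vectors.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORIES",
    "FeatureModel",
    "FeatureDistribution",
    "build_feature_model",
    "classify_region",
    "classify_regions",
    "generate_random_tiles",
    "feature_distribution",
    "dense_tile_fractions",
    "compare_feature_distributions",
]

# Fixed reporting order; the first six are gene-linked, intergenic is the
# fallback.  Tie-break precedence for equal overlap is 5UTR > 3UTR > exon >
# intron > promoter > downstream.
CATEGORIES = ["promoter", "5UTR", "exon", "intron", "3UTR", "downstream",
              "intergenic"]
_PRECEDENCE = ["5UTR", "3UTR", "exon", "intron", "promoter", "downstream"]


def _merge(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent [start, end) intervals (sorted input)."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


@dataclass
class FeatureModel:
    """Interval sets per category and chromosome, plus gene metadata.

    ``intervals[category][chrom]`` is an (m, 2) array of merged 0-based
    half-open intervals; ``genes`` has columns gene_id, chrom, strand,
    start, end.
    """

    genes: pd.DataFrame
    intervals: Dict[str, Dict[str, np.ndarray]]
    chrom_lengths: Dict[str, int]
    _cum: dict = field(default_factory=dict, repr=False)

    def category_bp(self, chrom: Optional[str] = None) -> pd.Series:
        """Total merged base pairs per gene-linked category."""
        out = {}
        for cat in CATEGORIES[:-1]:
            per = self.intervals.get(cat, {})
            items = per.items() if chrom is None else [(chrom, per.get(chrom, np.zeros((0, 2))))]
            out[cat] = int(sum((iv[:, 1] - iv[:, 0]).sum() for _, iv in items))
        return pd.Series(out)


def _overlap_lengths(starts: np.ndarray, ends: np.ndarray, iv: np.ndarray
                     ) -> np.ndarray:
    """Vectorised total overlap of each [start, end) query with interval set."""
    if len(iv) == 0:
        return np.zeros(len(starts), dtype=int)
    iv_s, iv_e = iv[:, 0], iv[:, 1]
    lens = iv_e - iv_s
    cum = np.concatenate([[0], np.cumsum(lens)])

    def cov_before(x):
        # total covered bp in [0, x)
        idx = np.searchsorted(iv_s, x, side="right")
        full = cum[idx]
        # subtract the part of the last-entered interval beyond x
        part = np.where(idx > 0, np.maximum(iv_e[idx - 1] - np.maximum(
            iv_s[idx - 1], x), 0), 0)
        # part counts coverage of interval idx-1 at/after x, but only when
        # that interval actually extends past x
        return full - np.where(idx > 0, np.minimum(part, lens[idx - 1]), 0)

    return cov_before(ends) - cov_before(starts)


def build_feature_model(gff3, chrom_lengths: Optional[Dict[str, int]] = None,
                        flank: int = 2000) -> FeatureModel:
    """Parse GFF3 gene models into a :class:`FeatureModel`.

    Uses the first mRNA of each gene; introns are the gene span minus its
    exons; UTR features are used when present (their sequence stays
    labelled exon at equal overlap only below UTRs in precedence).  GFF3
    1-based inclusive coordinates are converted to 0-based half-open.
    Chromosome lengths come from ``##sequence-region`` pragmas unless
    given explicitly; promoters and downstream windows are clipped to
    chromosome bounds.
    """
    import gffutils

    text = None
    path = None
    if isinstance(gff3, (str, Path)) and "\n" not in str(gff3):
        path = str(gff3)
        text = Path(path).read_text()
    else:
        text = str(gff3)
    lengths = dict(chrom_lengths or {})
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4 and parts[1] not in lengths:
                lengths[parts[1]] = int(parts[3])

    gene_rows = []
    raw: Dict[str, Dict[str, list]] = {c: {} for c in CATEGORIES[:-1]}
    has_features = any(line.strip() and not line.startswith("#")
                       for line in text.splitlines())
    if not has_features:
        return FeatureModel(
            pd.DataFrame(columns=["gene_id", "chrom", "strand", "start",
                                  "end"]),
            {c: {} for c in CATEGORIES[:-1]}, lengths)
    db = gffutils.create_db(text, ":memory:", from_string=True,
                            merge_strategy="create_unique", force=True)

    def add(cat, chrom, s0, e0):
        if e0 > s0:
            raw[cat].setdefault(chrom, []).append((s0, e0))

    for gene in db.features_of_type("gene"):
        chrom, strand = gene.seqid, gene.strand
        gs, ge = gene.start - 1, gene.end  # to 0-based half-open
        gene_rows.append({"gene_id": gene.id, "chrom": chrom,
                          "strand": strand, "start": gs, "end": ge})
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        exons = []
        for ex in db.children(parent, featuretype="exon"):
            es, ee = ex.start - 1, ex.end
            if es < gs or ee > ge:
                raise ValueError(
                    f"exon {ex.id} outside its gene {gene.id}")
            exons.append((es, ee))
        exons = _merge(np.asarray(exons) if exons
                       else np.zeros((0, 2), dtype=int))
        for es, ee in exons:
            add("exon", chrom, es, ee)
        # introns: gene span minus exons
        cursor = gs
        for es, ee in exons:
            add("intron", chrom, cursor, es)
            cursor = ee
        add("intron", chrom, cursor, ge)
        for ftype, cat in (("five_prime_UTR", "5UTR"),
                           ("three_prime_UTR", "3UTR")):
            for u in db.children(parent, featuretype=ftype):
                add(cat, chrom, u.start - 1, u.end)
        clen = lengths.get(chrom)
        if strand == "-":
            prom = (ge, ge + flank)
            down = (gs - flank, gs)
        else:
            prom = (gs - flank, gs)
            down = (ge, ge + flank)
        for cat, (s0, e0) in (("promoter", prom), ("downstream", down)):
            s0 = max(s0, 0)
            if clen is not None:
                e0 = min(e0, clen)
            add(cat, chrom, s0, e0)

    intervals = {
        cat: {chrom: _merge(np.asarray(ivs))
              for chrom, ivs in per.items()}
        for cat, per in raw.items()
    }
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "strand",
                                             "start", "end"])
    return FeatureModel(genes, intervals, lengths)


def classify_regions(tiles: pd.DataFrame, model: FeatureModel) -> pd.DataFrame:
    """Classify many tiles at once.

    ``tiles`` needs columns chrom, start, end (0-based half-open).
    Returns a copy with ``category`` and ``nearest_gene`` columns; the
    category has maximal overlap among the gene-linked categories, with
    ties broken by precedence, and tiles overlapping none of them are
    intergenic with the nearest gene by midpoint distance (or None).
    """
    out = tiles.copy().reset_index(drop=True)
    cats = np.full(len(out), "intergenic", dtype=object)
    nearest = np.full(len(out), None, dtype=object)
    for chrom, sub in out.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        overlaps = np.zeros((len(_PRECEDENCE), len(sub)), dtype=float)
        for ci, cat in enumerate(_PRECEDENCE):
            iv = model.intervals.get(cat, {}).get(chrom)
            if iv is not None and len(iv):
                overlaps[ci] = _overlap_lengths(starts, ends, iv)
        best = overlaps.argmax(axis=0)  # argmax honours precedence order
        any_overlap = overlaps.max(axis=0) > 0
        cats[idx[any_overlap]] = np.asarray(_PRECEDENCE, dtype=object)[
            best[any_overlap]]

        gsub = model.genes[model.genes["chrom"] == chrom]
        if len(gsub):
            gmid = ((gsub["start"] + gsub["end"]) / 2.0).to_numpy()
            order = np.argsort(gmid)
            gmid_sorted = gmid[order]
            gids = gsub["gene_id"].to_numpy()[order]
            tmid = (starts + ends) / 2.0
            j = np.clip(np.searchsorted(gmid_sorted, tmid), 0,
                        len(gmid_sorted) - 1)
            jlo = np.clip(j - 1, 0, len(gmid_sorted) - 1)
            pick = np.where(np.abs(gmid_sorted[j] - tmid)
                            <= np.abs(gmid_sorted[jlo] - tmid), j, jlo)
            nearest[idx] = gids[pick]
    out["category"] = cats
    out["nearest_gene"] = nearest
    return out


def classify_region(tile: Tuple[str, int, int], model: FeatureModel
                    ) -> Tuple[str, Optional[str]]:
    """Classify one (chrom, start, end) tile; see :func:`classify_regions`."""
    chrom, start, end = tile
    df = pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})
    res = classify_regions(df, model)
    return str(res["category"].iloc[0]), res["nearest_gene"].iloc[0]


def generate_random_tiles(model: FeatureModel, n_per_set: int = 39053,
                          n_sets: int = 6, seed: int = 0, tile: int = 100
                          ) -> List[pd.DataFrame]:
    """Uniform random ``tile``-bp windows, chromosomes weighted by length.

    Tiles may overlap each other and any feature; each of the ``n_sets``
    sets is an independent draw, reproducible from ``seed``.
    """
    if n_per_set < 1:
        raise ValueError("n_per_set must be positive")
    if not model.chrom_lengths:
        raise ValueError("model has no chromosome lengths")
    chroms = sorted(model.chrom_lengths)
    room = np.array([model.chrom_lengths[c] - tile + 1 for c in chroms],
                    dtype=float)
    if (room <= 0).all():
        raise ValueError("no chromosome can host a tile of this size")
    room = np.maximum(room, 0)
    weights = room / room.sum()
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        which = rng.choice(len(chroms), size=n_per_set, p=weights)
        starts = (rng.random(n_per_set) * room[which]).astype(int)
        sets.append(pd.DataFrame({
            "chrom": np.asarray(chroms, dtype=object)[which],
            "start": starts, "end": starts + tile,
        }))
    return sets


@dataclass
class FeatureDistribution:
    """Fractions of tiles per category (fixed CATEGORIES order)."""

    fractions: pd.Series
    n_tiles: int

    def __post_init__(self) -> None:
        self.fractions = self.fractions.reindex(CATEGORIES).fillna(0.0)
        if self.n_tiles > 0 and abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")


def feature_distribution(labels: Sequence[str]) -> FeatureDistribution:
    """Category fractions of a set of classified tiles."""
    s = pd.Series(labels)
    frac = s.value_counts(normalize=True)
    return FeatureDistribution(frac, len(s))


def dense_tile_fractions(model: FeatureModel, tile: int = 100
                         ) -> FeatureDistribution:
    """Exact category fractions of the dense non-overlapping tiling.

    Classifies every ``tile``-bp window of every chromosome; serves as the
    exact reference the random-tile null should match in expectation.
    """
    frames = []
    for chrom, clen in model.chrom_lengths.items():
        starts = np.arange(0, clen - tile + 1, tile)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                    "end": starts + tile}))
    dense = pd.concat(frames, ignore_index=True)
    labelled = classify_regions(dense, model)
    return feature_distribution(labelled["category"])


def compare_feature_distributions(observed: FeatureDistribution,
                                  reference: FeatureDistribution
                                  ) -> Tuple[float, float]:
    """Two-sample KS test between two category distributions.

    Categories are treated as ordered in the fixed reporting order; the
    statistic is the supremum difference of the two cumulative category
    distributions (so identical distributions give D = 0, p = 1, and fully
    disjoint mass at opposite ends gives D = 1).  The p-value is the
    two-sample KS p with the tile counts as sample sizes, computed by
    turning each distribution into its sample of category ordinals.
    """
    a = observed.fractions.to_numpy()
    b = reference.fractions.to_numpy()
    if len(a) != len(b):
        raise ValueError("category vectors differ in length")
    if observed.n_tiles < 1 or reference.n_tiles < 1:
        raise ValueError("both distributions need n_tiles >= 1")
    ca = np.round(a * observed.n_tiles).astype(int)
    cb = np.round(b * reference.n_tiles).astype(int)
    sample_a = np.repeat(np.arange(len(a)), ca)
    sample_b = np.repeat(np.arange(len(b)), cb)
    res = stats.ks_2samp(sample_a, sample_b, mode="asymp")
    return float(res.statistic), float(res.pvalue)
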