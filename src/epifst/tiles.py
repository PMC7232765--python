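"""CpG coverage parsing, 100-bp tiling, and differential methylation.

A bismark-style coverage file carries per-CpG methylated/unmethylated read
counts for one individual.  CpGs are depth-filtered, summed into
non-overlapping 100-bp tiles, and tiles occupied by enough individuals of
each group are tested for differential methylation with a binomial
logistic likelihood-ratio test and Benjamini–Hochberg adjustment.  A tile
is called a DMR when the coverage-pooled group percentages differ by at
least 15 points and q <= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CpGCoverage",
    "TileMatrix",
    "ClusterProjection",
    "read_coverage",
    "write_coverage",
    "filter_by_coverage",
    "make_tiles",
    "dmr_test",
    "cluster_and_project",
]

_COV_COLUMNS = ["chrom", "start", "end", "pct", "meth", "unmeth"]


@dataclass
class CpGCoverage:
    """Per-individual CpG read counts.

    ``records`` columns: chrom, pos (internal 0-based), meth, unmeth.
    """

    individual: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chrom", "pos", "meth", "unmeth"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"coverage records need columns {sorted(need)}")
        if (self.records[["meth", "unmeth"]].to_numpy() < 0).any():
            raise ValueError("negative read counts")
        dup = self.records.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError(
                f"duplicate CpG positions for {self.individual}: "
                f"{self.records.loc[dup, ['chrom', 'pos']].iloc[0].tolist()}")

    @property
    def n_sites(self) -> int:
        return len(self.records)


def read_coverage(path, dialect: str = "zero_based",
                  individual: Optional[str] = None) -> CpGCoverage:
    """Parse a 6-column coverage TSV into internal 0-based coordinates.

    ``dialect`` is ``zero_based`` (column 2 is already 0-based, as written
    by methylation extractors run with a zero-based flag) or ``one_based``
    (column 2 is 1-based and is shifted down by one).  The percent column
    is ignored; fractions are always recomputed from the counts.  An empty
    file yields an empty coverage with a warning.
    """
    if dialect not in ("zero_based", "one_based"):
        raise ValueError(f"unknown coverage dialect {dialect!r}")
    path = str(path)
    name = individual or path.rsplit("/", 1)[-1].split(".")[0]
    try:
        raw = pd.read_csv(path, sep="\t", header=None, names=_COV_COLUMNS,
                          dtype={"chrom": str}, comment=None)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=_COV_COLUMNS)
    if raw.empty:
        warnings.warn(f"coverage file {path} is empty", stacklevel=2)
        return CpGCoverage(name, pd.DataFrame(
            columns=["chrom", "pos", "meth", "unmeth"]))
    for col in ("start", "end", "meth", "unmeth"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: malformed line {lineno} "
                             f"(non-integer {col!r} field)")
        raw[col] = vals.astype(int)
    if (raw[["meth", "unmeth"]].to_numpy() < 0).any():
        lineno = int(((raw["meth"] < 0) | (raw["unmeth"] < 0)).idxmax()) + 1
        raise ValueError(f"{path}: negative count on line {lineno}")
    pos = raw["start"] if dialect == "zero_based" else raw["start"] - 1
    rec = pd.DataFrame({"chrom": raw["chrom"], "pos": pos.astype(int),
                        "meth": raw["meth"], "unmeth": raw["unmeth"]})
    return CpGCoverage(name, rec)


def write_coverage(cov: CpGCoverage, path, dialect: str = "zero_based") -> None:
    """Write coverage back out in the 6-column TSV layout."""
    r = cov.records
    shift = 0 if dialect == "zero_based" else 1
    total = r["meth"] + r["unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * r["meth"] / total, 0.0)
    out = pd.DataFrame({
        "chrom": r["chrom"],
        "start": r["pos"] + shift,
        "end": r["pos"] + 1,
        "pct": [f"{v:.6g}" for v in pct],
        "meth": r["meth"],
        "unmeth": r["unmeth"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def filter_by_coverage(cov: CpGCoverage, min_reads: int = 10) -> CpGCoverage:
    """Drop CpGs with fewer than ``min_reads`` total reads (inclusive keep)."""
    r = cov.records
    keep = (r["meth"] + r["unmeth"]) >= min_reads
    return CpGCoverage(cov.individual, r.loc[keep].reset_index(drop=True))


@dataclass
class TileMatrix:
    """Pooled per-individual read counts over non-overlapping tiles.

    ``meth`` and ``total`` are (n_tiles, n_individuals) integer arrays;
    ``keys`` has one row per tile (chrom, start, end, 0-based half-open).
    """

    keys: pd.DataFrame
    individuals: list
    meth: np.ndarray
    total: np.ndarray
    groups: Dict[str, str]

    @property
    def n_tiles(self) -> int:
        return len(self.keys)

    def fractions(self) -> np.ndarray:
        """Per-individual tile methylation fractions (NaN where no reads)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / self.total, np.nan)

    def group_members(self, group: str) -> np.ndarray:
        return np.array([self.groups[i] == group for i in self.individuals])

    def tile_ids(self) -> pd.Series:
        k = self.keys
        return (k["chrom"].astype(str) + ":" + k["start"].astype(str)
                + "-" + k["end"].astype(str))


def make_tiles(covs: Mapping[str, CpGCoverage], groups: Mapping[str, str],
               tile: int = 100, step: int = 100,
               min_individuals_per_group: int = 8) -> TileMatrix:
    """Sum CpG counts into ``tile``-bp windows anchored at coordinate 0.

    Only non-overlapping tiling is supported (``step`` must equal
    ``tile``).  A tile is retained when, for every group, at least
    ``min_individuals_per_group`` of its members have at least one read in
    the tile.  Counts are conserved: summing a retained tile's counts over
    individuals reproduces the underlying CpG counts exactly.
    """
    if tile != step:
        raise ValueError("only non-overlapping tiling supported (tile == step)")
    if tile < 1:
        raise ValueError("tile size must be positive")
    group_names = sorted(set(groups.values()))
    sizes = pd.Series(list(groups.values())).value_counts()
    for g in group_names:
        if sizes.get(g, 0) < min_individuals_per_group:
            raise ValueError(
                f"group {g!r} has {sizes.get(g, 0)} members, fewer than "
                f"min_individuals_per_group={min_individuals_per_group}")
    individuals = [i for i in covs if i in groups]
    if not individuals:
        raise ValueError("no individual is present in both covs and groups")

    per_ind = []
    for ind in individuals:
        r = covs[ind].records
        if r.empty:
            per_ind.append(pd.DataFrame(columns=["chrom", "start", "meth",
                                                 "unmeth"]))
            continue
        g = r.assign(start=(r["pos"] // tile) * tile).groupby(
            ["chrom", "start"], sort=False, as_index=False)[["meth", "unmeth"]
                                                            ].sum()
        per_ind.append(g)

    all_keys = (pd.concat([g[["chrom", "start"]] for g in per_ind])
                .drop_duplicates().sort_values(["chrom", "start"])
                .reset_index(drop=True))
    if all_keys.empty:
        keys = all_keys.assign(end=pd.Series(dtype=int))
        return TileMatrix(keys, individuals,
                          np.zeros((0, len(individuals)), dtype=int),
                          np.zeros((0, len(individuals)), dtype=int),
                          dict(groups))
    index = pd.MultiIndex.from_frame(all_keys)
    T, N = len(all_keys), len(individuals)
    meth = np.zeros((T, N), dtype=np.int64)
    total = np.zeros((T, N), dtype=np.int64)
    for j, g in enumerate(per_ind):
        if g.empty:
            continue
        loc = index.get_indexer(pd.MultiIndex.from_frame(g[["chrom", "start"]]))
        meth[loc, j] = g["meth"].to_numpy()
        total[loc, j] = g["meth"].to_numpy() + g["unmeth"].to_numpy()

    covered = total > 0
    keep = np.ones(T, dtype=bool)
    for gname in group_names:
        members = np.array([groups[i] == gname for i in individuals])
        keep &= covered[:, members].sum(axis=1) >= min_individuals_per_group
    keys = all_keys.loc[keep].reset_index(drop=True)
    keys["end"] = keys["start"] + tile
    return TileMatrix(keys, individuals, meth[keep], total[keep], dict(groups))


def _pooled_loglik(meth: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood at the pooled MLE, per tile."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(total > 0, meth / total, 0.0)
    return xlogy(meth, p) + xlogy(total - meth, 1.0 - p)


def dmr_test(tiles: TileMatrix, group1: str, group2: str,
             diff_threshold: float = 15.0, q_threshold: float = 0.05
             ) -> pd.DataFrame:
    """Tile-level differential methylation between two groups.

    The test is a likelihood-ratio test of a binomial logistic model with
    a single group factor on the per-individual (methylated, total)
    counts; because the group-wise MLEs are the coverage-pooled fractions,
    the deviance reduces to a closed form on pooled counts.  When either
    group has a single member the p-value comes from Fisher's exact test
    on the pooled 2x2 table instead.  p-values are BH-adjusted across all
    tested tiles of the comparison.

    Returns one row per tested tile: tile id, per-group pooled percent,
    ``meth_diff`` (group1 − group2, percentage points), p, q and
    ``call`` in {hyper, hypo, ns} oriented relative to ``group1``.
    """
    m1mask = tiles.group_members(group1)
    m2mask = tiles.group_members(group2)
    if not m1mask.any() or not m2mask.any():
        raise ValueError("both groups must have members in the tile matrix")

    m1 = tiles.meth[:, m1mask].sum(axis=1).astype(float)
    t1 = tiles.total[:, m1mask].sum(axis=1).astype(float)
    m2 = tiles.meth[:, m2mask].sum(axis=1).astype(float)
    t2 = tiles.total[:, m2mask].sum(axis=1).astype(float)

    ok = (t1 > 0) & (t2 > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} tile(s) with zero total reads in a group "
                      "excluded from testing", stacklevel=2)
    m1, t1, m2, t2 = m1[ok], t1[ok], m2[ok], t2[ok]

    if min(int(m1mask.sum()), int(m2mask.sum())) == 1:
        pvals = np.array([
            stats.fisher_exact([[mm1, tt1 - mm1], [mm2, tt2 - mm2]])[1]
            for mm1, tt1, mm2, tt2 in zip(m1, t1, m2, t2)])
    else:
        ll_alt = _pooled_loglik(m1, t1) + _pooled_loglik(m2, t2)
        ll_null = _pooled_loglik(m1 + m2, t1 + t2)
        g = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
        pvals = stats.chi2.sf(g, df=1)

    qvals = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    pct1 = 100.0 * m1 / t1
    pct2 = 100.0 * m2 / t2
    diff = pct1 - pct2
    sig = (np.abs(diff) >= diff_threshold) & (qvals <= q_threshold)
    call = np.where(sig, np.where(diff > 0, "hyper", "hypo"), "ns")

    out = tiles.keys.loc[ok].reset_index(drop=True).copy()
    out["tile"] = (out["chrom"].astype(str) + ":" + out["start"].astype(str)
                   + "-" + out["end"].astype(str))
    out["pct_group1"], out["pct_group2"] = pct1, pct2
    out["meth_diff"] = diff
    out["p"], out["q"], out["call"] = pvals, qvals, call
    out.attrs["group1"], out.attrs["group2"] = group1, group2
    return out


@dataclass
class ClusterProjection:
    """Ward dendrogram and principal-component scores of sample methylomes."""

    samples: list
    distance: np.ndarray          # condensed 1 - Pearson distances
    linkage: np.ndarray           # scipy linkage matrix (Ward)
    pc_scores: pd.DataFrame       # samples x components
    explained_variance_ratio: np.ndarray

    def cut(self, k: int) -> np.ndarray:
        from scipy.cluster.hierarchy import fcluster
        return fcluster(self.linkage, k, criterion="maxclust")


def cluster_and_project(tiles: TileMatrix, n_components: int = 2
                        ) -> ClusterProjection:
    """Cluster samples on shared tiles and project them on PCs.

    Uses only tiles covered in every sample; the distance is 1 − Pearson
    correlation of per-sample fraction vectors, clustered with Ward
    linkage; PC scores come from the SVD of the centred fraction matrix.
    """
    frac = tiles.fractions()
    shared = ~np.isnan(frac).any(axis=1)
    X = frac[shared].T  # samples x tiles
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 tiles shared by all samples")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = [s for s, z in zip(tiles.individuals, sd == 0) if z]
        raise ValueError(f"constant methylation vector (undefined Pearson "
                         f"correlation) for sample(s): {bad}")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    iu = np.triu_indices_from(dist, k=1)
    condensed = np.maximum(dist[iu], 0.0)
    Z = linkage(condensed, method="ward")

    centred = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    evr = (s ** 2) / (s ** 2).sum() if (s ** 2).sum() > 0 else s
    pc = pd.DataFrame(scores, index=tiles.individuals,
                      columns=[f"PC{i + 1}" for i in range(k)])
    return ClusterProjection(list(tiles.individuals), condensed, Z, pc, evr[:k])
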