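"""Weir & Cockerham theta, locus filters, and gene-level F_ST."""

import numpy as np
import pandas as pd
import pytest

from epifst import (GenotypeMatrix, filter_loci, fst_per_locus,
                    gene_weighted_fst, mean_fst, wc_theta)

from oracles import wc84_theta_scalar


class TestWcTheta:
    def test_fixed_difference_gives_theta_one(self):
        res = wc_theta(n=[10, 10], p=[1.0, 0.0], h=[0.0, 0.0])
        assert res.theta == pytest.approx(1.0, abs=1e-12)

    def test_globally_monomorphic_theta_undefined(self):
        res = wc_theta(n=[10, 10], p=[0.0, 0.0], h=[0.0, 0.0])
        assert np.isnan(res.theta)

    def test_equal_frequencies_match_oracle(self):
        res = wc_theta(n=[10, 10], p=[0.5, 0.5], h=[0.5, 0.5])
        a, b, c, theta = wc84_theta_scalar([10, 10], [0.5, 0.5], [0.5, 0.5])
        assert res.theta == pytest.approx(theta, abs=1e-12)
        assert abs(res.theta) < 0.1  # near zero, sign unconstrained

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            r = rng.integers(2, 6)
            n = rng.integers(2, 30, size=r).astype(float)
            p = rng.random(r)
            # heterozygosity bounded by feasibility: h <= 2p(1-p) grid-free
            h = rng.random(r) * np.minimum(2 * p, 2 * (1 - p))
            got = wc_theta(n, p, h)
            a, b, c, theta = wc84_theta_scalar(n, p, h)
            assert got.a == pytest.approx(a, abs=1e-12)
            assert got.b == pytest.approx(b, abs=1e-12)
            assert got.c == pytest.approx(c, abs=1e-12)
            if np.isnan(theta):
                assert np.isnan(got.theta)
            else:
                assert got.theta == pytest.approx(theta, abs=1e-12)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            wc_theta(n=[10], p=[0.5], h=[0.5])

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            wc_theta(n=[10, 10], p=[-0.1, 0.5], h=[0.0, 0.0])


def _matrix(calls, pops=None, positions=None, rad_ids=None):
    calls = np.asarray(calls, dtype=float)
    L, N = calls.shape
    pops = pops if pops is not None else ["A"] * (N // 2) + ["B"] * (N - N // 2)
    loci = pd.DataFrame({
        "chrom": "chr1",
        "pos": positions if positions is not None else np.arange(L) * 100,
        "rad_id": rad_ids if rad_ids is not None else [f"r{i}" for i in range(L)],
    })
    return GenotypeMatrix(loci, [f"i{j}" for j in range(N)],
                          np.asarray(pops, dtype=object), calls)


class TestFilterLoci:
    def test_low_presence_everywhere_dropped(self):
        # 3/5 = 60% called in each population: below the 65% rule
        row = [1, 1, 0, np.nan, np.nan] * 2
        m = _matrix([row])
        assert filter_loci(m).n_loci == 0

    def test_low_maf_dropped(self):
        # minor allele count 4 of 100 called alleles -> MAF 0.04
        calls = np.zeros((1, 50))
        calls[0, :4] = 1.0
        m = _matrix(calls.tolist())
        assert filter_loci(m).n_loci == 0
        assert filter_loci(m, min_maf=0.04).n_loci == 1

    def test_single_snp_per_rad_locus(self):
        calls = np.tile([0, 1, 2, 1, 0, 1, 2, 1], (3, 1))
        m = _matrix(calls, rad_ids=["radX"] * 3)
        out = filter_loci(m)
        assert out.n_loci == 1
        assert out.loci["pos"].iloc[0] == 0  # first SNP kept

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(40, 20)).astype(float)
        calls[rng.random(calls.shape) < 0.3] = np.nan
        m = _matrix(calls)
        once = filter_loci(m)
        twice = filter_loci(once)
        assert once.n_loci <= m.n_loci
        assert twice.n_loci == once.n_loci
        assert np.array_equal(once.calls, twice.calls, equal_nan=True)


class TestMeanFst:
    def test_all_theta_one(self):
        tab = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0],
                            "c": [0.0, 0.0], "theta": [1.0, 1.0]})
        assert mean_fst(tab) == (1.0, 1.0)

    def test_two_component_example(self):
        # loci {a=1,b=0,c=1} and {a=0,b=0,c=1}: thetas 0.5 and 0
        tab = pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 0.0],
                            "c": [1.0, 1.0], "theta": [0.5, 0.0]})
        mean_theta, ratio = mean_fst(tab)
        assert mean_theta == pytest.approx(0.25)
        assert ratio == pytest.approx(1.0 / 3.0)

    def test_all_undefined_raises(self):
        tab = pd.DataFrame({"a": [np.nan], "b": [np.nan], "c": [np.nan],
                            "theta": [np.nan]})
        with pytest.raises(ValueError):
            mean_fst(tab)


class TestGeneWeightedFst:
    GENES = pd.DataFrame({
        "gene_id": ["g1"], "chrom": ["chr1"], "start": [5000], "end": [8000],
    })

    def test_single_locus_gene_equals_locus_theta(self):
        tab = pd.DataFrame({"chrom": ["chr1"], "pos": [6000], "a": [0.3],
                            "b": [0.1], "c": [0.6], "theta": [0.3]})
        out = gene_weighted_fst(tab, self.GENES)
        assert out["fst"].iloc[0] == pytest.approx(0.3)

    def test_two_locus_weighting(self):
        tab = pd.DataFrame({"chrom": "chr1", "pos": [6000, 7000],
                            "a": [1.0, 0.0], "b": [0.0, 0.0],
                            "c": [1.0, 1.0], "theta": [0.5, 0.0]})
        out = gene_weighted_fst(tab, self.GENES)
        assert out["fst"].iloc[0] == pytest.approx(1.0 / 3.0)

    def test_promoter_locus_assigned_to_gene(self):
        # 1,500 bp upstream of the gene start: inside the 2-kb promoter
        tab = pd.DataFrame({"chrom": ["chr1"], "pos": [3500], "a": [0.2],
                            "b": [0.0], "c": [0.8], "theta": [0.2]})
        out = gene_weighted_fst(tab, self.GENES)
        assert list(out["gene_id"]) == ["g1"]

    def test_gene_without_loci_absent(self):
        tab = pd.DataFrame({"chrom": ["chr1"], "pos": [15000], "a": [0.2],
                            "b": [0.0], "c": [0.8], "theta": [0.2]})
        assert gene_weighted_fst(tab, self.GENES).empty


def test_fst_per_locus_handles_missing_and_matches_scalar_path():
    rng = np.random.default_rng(5)
    calls = rng.integers(0, 3, size=(30, 24)).astype(float)
    calls[rng.random(calls.shape) < 0.2] = np.nan
    pops = ["A"] * 8 + ["B"] * 8 + ["C"] * 8
    m = _matrix(calls, pops=pops)
    tab = fst_per_locus(m)
    # re-derive one locus by hand through the scalar entry point
    i = 7
    n, p, h = [], [], []
    for pop in ("A", "B", "C"):
        sub = calls[i, np.asarray(pops) == pop]
        sub = sub[~np.isnan(sub)]
        n.append(len(sub))
        p.append(sub.sum() / (2 * len(sub)))
        h.append((sub == 1).mean())
    expect = wc_theta(n, p, h).theta
    got = tab["theta"].iloc[i]
    if np.isnan(expect):
        assert np.isnan(got)
    else:
        assert got == pytest.approx(expect, abs=1e-12)
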