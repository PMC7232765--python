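"""Coverage parsing, tiling, DMR calling and sample clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from epifst import (CpGCoverage, cluster_and_project, dmr_test,
                    filter_by_coverage, make_tiles, read_coverage,
                    write_coverage)

from oracles import bh_stepup


def _cov(ind, rows):
    return CpGCoverage(ind, pd.DataFrame(
        rows, columns=["chrom", "pos", "meth", "unmeth"]))


class TestReadCoverage:
    def test_zero_based_parse(self, tmp_path):
        p = tmp_path / "a.cov"
        p.write_text("chr1\t100\t101\t50.0\t5\t5\n")
        cov = read_coverage(p, dialect="zero_based")
        assert cov.records.iloc[0].tolist() == ["chr1", 100, 5, 5]

    def test_one_based_shifts_position(self, tmp_path):
        p = tmp_path / "a.cov"
        p.write_text("chr1\t101\t101\t50.0\t5\t5\n")
        cov = read_coverage(p, dialect="one_based")
        assert cov.records["pos"].iloc[0] == 100

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "a.cov"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            cov = read_coverage(p)
        assert cov.n_sites == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.cov"
        p.write_text("chr1\t100\t101\t50.0\t5\t5\n"
                     "chr1\tnope\t201\t10.0\t1\t9\n")
        with pytest.raises(ValueError, match="line 2"):
            read_coverage(p)

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "a.cov"
        p.write_text("chr1\t100\t101\t50.0\t-5\t5\n")
        with pytest.raises(ValueError, match="negative|line 1"):
            read_coverage(p)

    def test_roundtrip_both_dialects(self, tmp_path):
        cov = _cov("x", [("chr1", 99, 3, 7), ("chr2", 0, 10, 0)])
        for dialect in ("zero_based", "one_based"):
            p = tmp_path / f"{dialect}.cov"
            write_coverage(cov, p, dialect=dialect)
            back = read_coverage(p, dialect=dialect, individual="x")
            pd.testing.assert_frame_equal(back.records, cov.records)


class TestFilterByCoverage:
    @pytest.mark.parametrize("meth,unmeth,kept", [
        (4, 5, False),   # 9 reads: below threshold
        (5, 5, True),    # exactly 10: "at least" is inclusive
        (100, 0, True),
    ])
    def test_threshold_boundary(self, meth, unmeth, kept):
        cov = _cov("x", [("chr1", 1, meth, unmeth)])
        assert filter_by_coverage(cov, 10).n_sites == (1 if kept else 0)

    def test_zero_threshold_is_identity(self):
        cov = _cov("x", [("chr1", 1, 0, 0), ("chr1", 2, 1, 1)])
        assert filter_by_coverage(cov, 0).n_sites == 2


def _group_fixture(n_per_group=8, tile_rows=None):
    """Two groups of n individuals sharing one covered tile."""
    covs, groups = {}, {}
    for g, base in (("G1", 0), ("G2", 100)):
        for j in range(n_per_group):
            ind = f"{g}_{j}"
            covs[ind] = _cov(ind, tile_rows or [("chr1", 105, 5, 5)])
            groups[ind] = g
    return covs, groups


class TestMakeTiles:
    def test_two_cpg_pooling(self):
        covs, groups = _group_fixture(
            tile_rows=[("chr1", 105, 5, 5), ("chr1", 180, 2, 8)])
        tm = make_tiles(covs, groups)
        assert tm.keys.iloc[0][["start", "end"]].tolist() == [100, 200]
        assert tm.meth[0, 0] == 7 and tm.total[0, 0] == 20
        assert tm.fractions()[0, 0] == pytest.approx(0.35)

    def test_occupancy_rule_excludes_sparse_tile(self):
        covs, groups = _group_fixture(n_per_group=10)
        # empty out 3 of the 10 G1 individuals: only 7 < 8 remain covered
        for j in range(3):
            covs[f"G1_{j}"] = _cov(f"G1_{j}", [])
        tm = make_tiles(covs, groups, min_individuals_per_group=8)
        assert tm.n_tiles == 0

    def test_no_cpgs_no_tiles(self):
        covs, groups = _group_fixture()
        covs = {i: _cov(i, []) for i in covs}
        assert make_tiles(covs, groups).n_tiles == 0

    def test_overlapping_tiling_rejected(self):
        covs, groups = _group_fixture()
        with pytest.raises(ValueError, match="non-overlapping"):
            make_tiles(covs, groups, tile=100, step=50)

    def test_small_group_rejected(self):
        covs, groups = _group_fixture(n_per_group=5)
        with pytest.raises(ValueError, match="fewer"):
            make_tiles(covs, groups, min_individuals_per_group=8)

    def test_count_conservation_on_random_fixture(self):
        rng = np.random.default_rng(11)
        covs, groups = {}, {}
        for g in ("G1", "G2"):
            for j in range(8):
                ind = f"{g}{j}"
                pos = rng.choice(5000, size=200, replace=False)
                m = rng.integers(0, 20, size=200)
                u = rng.integers(0, 20, size=200)
                covs[ind] = _cov(ind, list(zip(["chr1"] * 200, pos, m, u)))
                groups[ind] = g
        tm = make_tiles(covs, groups, min_individuals_per_group=1)
        for j, ind in enumerate(tm.individuals):
            rec = covs[ind].records
            assert tm.meth[:, j].sum() == rec["meth"].sum()
            assert (tm.total[:, j].sum()
                    == (rec["meth"] + rec["unmeth"]).sum())


class TestDmrTest:
    def test_identical_groups_not_significant(self):
        covs, groups = _group_fixture()
        tm = make_tiles(covs, groups)
        res = dmr_test(tm, "G1", "G2")
        assert res["meth_diff"].iloc[0] == 0.0
        assert res["call"].iloc[0] == "ns"

    def test_strong_two_sample_difference_called_hyper(self):
        # two samples each 9m/1u vs two samples each 1m/9u
        covs, groups = {}, {}
        for j in range(2):
            covs[f"a{j}"] = _cov(f"a{j}", [("chr1", 10, 9, 1)])
            groups[f"a{j}"] = "G1"
            covs[f"b{j}"] = _cov(f"b{j}", [("chr1", 10, 1, 9)])
            groups[f"b{j}"] = "G2"
        tm = make_tiles(covs, groups, min_individuals_per_group=2)
        res = dmr_test(tm, "G1", "G2")
        assert res["meth_diff"].iloc[0] == pytest.approx(80.0)
        # independent exact-test oracle on the pooled 18/2 vs 2/18 table
        _, p_exact = stats.fisher_exact([[18, 2], [2, 18]])
        assert p_exact <= 0.05
        assert res["q"].iloc[0] <= 0.05
        assert res["call"].iloc[0] == "hyper"

    def test_small_difference_never_called(self):
        # 10-point difference at arbitrarily deep coverage stays ns
        covs, groups = _group_fixture(
            tile_rows=[("chr1", 10, 50_000, 50_000)])
        for i in groups:
            if groups[i] == "G2":
                covs[i] = _cov(i, [("chr1", 10, 40_000, 60_000)])
        tm = make_tiles(covs, groups)
        res = dmr_test(tm, "G1", "G2")
        assert res["meth_diff"].iloc[0] == pytest.approx(10.0)
        assert res["q"].iloc[0] < 1e-10  # highly significant, still ns
        assert res["call"].iloc[0] == "ns"

    def test_single_sample_group_uses_exact_test(self):
        covs = {"a": _cov("a", [("chr1", 10, 18, 2)]),
                "b": _cov("b", [("chr1", 10, 2, 18)])}
        groups = {"a": "G1", "b": "G2"}
        tm = make_tiles(covs, groups, min_individuals_per_group=1)
        res = dmr_test(tm, "G1", "G2")
        _, p_exact = stats.fisher_exact([[18, 2], [2, 18]])
        assert res["p"].iloc[0] == pytest.approx(p_exact, rel=1e-12)

    def test_lrt_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        covs, groups = {}, {}
        for g in ("G1", "G2"):
            for j in range(8):
                ind = f"{g}{j}"
                rows = []
                for t in range(10):
                    d = int(rng.integers(10, 40))
                    m = int(rng.binomial(d, 0.5 if g == "G1" else 0.6))
                    rows.append(("chr1", t * 100 + 5, m, d - m))
                covs[ind] = _cov(ind, rows)
                groups[ind] = g
        tm = make_tiles(covs, groups)
        res = dmr_test(tm, "G1", "G2")
        g1 = tm.group_members("G1")
        for t in range(tm.n_tiles):
            endog = np.column_stack([tm.meth[t], tm.total[t] - tm.meth[t]])
            x = sm.add_constant(g1.astype(float))
            full = sm.GLM(endog, x, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((len(endog), 1)),
                          family=sm.families.Binomial()).fit()
            g_stat = 2 * (full.llf - null.llf)
            p_glm = stats.chi2.sf(max(g_stat, 0.0), 1)
            assert res["p"].iloc[t] == pytest.approx(p_glm, abs=1e-8)

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(7)
        covs, groups = {}, {}
        for g, pbase in (("G1", 0.35), ("G2", 0.6)):
            for j in range(8):
                ind = f"{g}{j}"
                rows = []
                for t in range(50):
                    d = int(rng.integers(10, 30))
                    m = int(rng.binomial(d, pbase + rng.normal(0, 0.05)))
                    rows.append(("chr1", t * 100 + 1, m, d - m))
                covs[ind] = _cov(ind, rows)
                groups[ind] = g
        tm = make_tiles(covs, groups)
        base = (dmr_test(tm, "G1", "G2", 15, 0.05)["call"] != "ns").sum()
        for diff, q in [(20, 0.05), (15, 0.01), (30, 0.001)]:
            tighter = (dmr_test(tm, "G1", "G2", diff, q)["call"] != "ns").sum()
            assert tighter <= base


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=60))
def test_bh_matches_stepup_oracle(pvals):
    ours = multipletests(pvals, method="fdr_bh")[1]
    expected = bh_stepup(pvals)
    assert np.allclose(ours, expected, atol=1e-12)


class TestClusterAndProject:
    def _fixture(self, shift=0.4, noise=0.02, n=5, tiles=40, seed=0):
        # group effect varies across tiles so correlation distance sees it
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.2, 0.5, size=tiles)
        covs, groups = {}, {}
        for g in ("G1", "G2"):
            for j in range(n):
                ind = f"{g}{j}"
                rows = []
                for t in range(tiles):
                    eff = shift if (g == "G2" and t % 2 == 0) else 0.0
                    frac = np.clip(base[t] + eff + rng.normal(0, noise), 0, 1)
                    d = 50
                    m = int(round(frac * d))
                    rows.append(("chr1", t * 100 + 3, m, d - m))
                covs[ind] = _cov(ind, rows)
                groups[ind] = g
        return make_tiles(covs, groups, min_individuals_per_group=2)

    def test_identical_samples_merge_first(self):
        tm = self._fixture(n=3)
        tm.meth[:, 1] = tm.meth[:, 0]
        tm.total[:, 1] = tm.total[:, 0]
        cp = cluster_and_project(tm)
        i, j = int(cp.linkage[0, 0]), int(cp.linkage[0, 1])
        assert {i, j} == {0, 1}           # the identical pair merges first
        assert cp.linkage[0, 2] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(cp.pc_scores.iloc[0], cp.pc_scores.iloc[1])

    def test_two_group_fixture_recovered_exactly(self):
        tm = self._fixture()
        cp = cluster_and_project(tm)
        labels = cp.cut(2)
        truth = np.array([tm.groups[i] == "G1" for i in cp.samples])
        assert ((labels[truth] == labels[truth][0]).all()
                and (labels[~truth] == labels[~truth][0]).all()
                and labels[truth][0] != labels[~truth][0])

    def test_pc_scores_invariant_to_tile_order(self):
        tm = self._fixture()
        cp1 = cluster_and_project(tm)
        rng = np.random.default_rng(1)
        perm = rng.permutation(tm.n_tiles)
        tm2 = type(tm)(tm.keys.iloc[perm].reset_index(drop=True),
                       tm.individuals, tm.meth[perm], tm.total[perm],
                       tm.groups)
        cp2 = cluster_and_project(tm2)
        for k in cp1.pc_scores.columns:
            a, b = cp1.pc_scores[k].values, cp2.pc_scores[k].values
            assert np.allclose(a, b, atol=1e-9) or np.allclose(a, -b,
                                                               atol=1e-9)

    def test_constant_sample_raises_with_name(self):
        tm = self._fixture(n=2)
        tm.meth[:, 0] = 0
        with pytest.raises(ValueError, match="G10"):
            cluster_and_project(tm)
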