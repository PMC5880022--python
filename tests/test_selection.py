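"""SNP selection filter, dataset merge, RSP windows and bootstrap test."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from methvar.selection import (
    STAT_COLUMNS,
    SelectionThresholds,
    bootstrap_mean_test,
    define_rsp_cpgs,
    filter_dbpshp,
    gerp_compare_groups,
    merge_snp_datasets,
)

PASSING = {
    "DAF": 0.10, "GFHOM1": 0.01, "GFHET": 0.10, "HWE2": 0.001, "HET": 0.3,
    "PI": 0.2, "DDAF": 0.3, "TD": -1.0, "FST1": 0.10, "UIHS": 2.0,
    "UXPEHH": 1.5, "XPCLR": 6.0,
}
# a value that violates exactly the named criterion
VIOLATIONS = {
    "DAF": 0.05, "GFHOM1": 0.001, "GFHET": 0.02, "HWE2": 0.00005, "HET": 0.6,
    "PI": 0.7, "DDAF": 0.2, "TD": 0.5, "FST1": 0.04, "UIHS": 1.5,
    "UXPEHH": 0.9, "XPCLR": 5.0,
}


def snp_row(rsid="rs1", chrom="chr1", pos=100, **overrides):
    row = {"rsid": rsid, "chrom": chrom, "pos": pos, **PASSING}
    row.update(overrides)
    return row


class TestFilter:
    def test_fully_passing_record_passes(self):
        assert len(filter_dbpshp(pd.DataFrame([snp_row()]))) == 1

    def test_positive_tajimas_d_fails(self):
        assert filter_dbpshp(pd.DataFrame([snp_row(TD=0.5)])).empty

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["rsid", "chrom", "pos", *STAT_COLUMNS])
        assert filter_dbpshp(empty).empty

    @pytest.mark.parametrize("stat", STAT_COLUMNS)
    def test_single_criterion_violation_fails(self, stat):
        row = snp_row(**{stat: VIOLATIONS[stat]})
        assert filter_dbpshp(pd.DataFrame([row])).empty

    def test_missing_statistic_fails(self):
        assert filter_dbpshp(pd.DataFrame([snp_row(DAF=np.nan)])).empty

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SelectionThresholds({"BOGUS": ("gt", 1.0)})

    def test_output_is_subset_of_input(self):
        rng = np.random.default_rng(0)
        rows = [snp_row(rsid=f"rs{i}", TD=float(rng.normal())) for i in range(40)]
        snps = pd.DataFrame(rows)
        out = filter_dbpshp(snps)
        assert set(out["rsid"]) <= set(snps["rsid"])


class TestMerge:
    def test_disjoint_union(self):
        a = pd.DataFrame([snp_row(rsid=f"rs{i}", pos=i) for i in range(3)])
        b = pd.DataFrame([snp_row(rsid=f"rs{i}", pos=i) for i in range(3, 7)])
        merged, n_dedup = merge_snp_datasets(a, b)
        assert len(merged) == 7 and n_dedup == 0

    def test_identical_sets_idempotent(self):
        a = pd.DataFrame([snp_row(rsid=f"rs{i}", pos=i) for i in range(4)])
        merged, n_dedup = merge_snp_datasets(a, a.copy())
        assert len(merged) == 4 and n_dedup == 4

    def test_duplicate_keeps_passing_copy(self):
        a = pd.DataFrame([
            snp_row(rsid="rs1", pos=10, TD=0.5),   # fails
            snp_row(rsid="rs2", pos=20),
            snp_row(rsid="rs3", pos=30, DAF=0.01),  # fails
        ])
        b = pd.DataFrame([
            snp_row(rsid="rs1", pos=10),            # passes -> kept
            snp_row(rsid="rs3", pos=30, DAF=0.02),  # also fails -> first kept
        ])
        merged, n_dedup = merge_snp_datasets(a, b)
        assert n_dedup == 2
        by_rsid = merged.set_index("rsid")
        assert by_rsid.loc["rs1", "TD"] == PASSING["TD"]
        assert by_rsid.loc["rs3", "DAF"] == 0.01

    def test_conflicting_positions_rejected(self):
        a = pd.DataFrame([snp_row(rsid="rs1", pos=10)])
        b = pd.DataFrame([snp_row(rsid="rs1", pos=99)])
        with pytest.raises(ValueError, match="conflicting"):
            merge_snp_datasets(a, b)


class TestRspWindows:
    def test_probe_at_snp_position_is_rsp(self):
        snps = pd.DataFrame([snp_row(pos=500)])
        manifest = pd.DataFrame({"probe": ["p"], "chrom": ["chr1"], "pos": [500]})
        out = define_rsp_cpgs(snps, manifest)
        assert out["rsp"].iloc[0]
        assert out["support"].iloc[0] == "rs1"

    def test_distant_probe_is_not_rsp(self):
        snps = pd.DataFrame([snp_row(pos=500)])
        manifest = pd.DataFrame({"probe": ["p"], "chrom": ["chr1"], "pos": [5500]})
        assert not define_rsp_cpgs(snps, manifest, half_window=1000)["rsp"].iloc[0]

    def test_matches_distance_oracle(self):
        rng = np.random.default_rng(9)
        snps = pd.DataFrame([snp_row(rsid=f"rs{i}",
                                     chrom=rng.choice(["chr1", "chr2"]),
                                     pos=int(rng.integers(1, 50_000)))
                             for i in range(20)])
        manifest = pd.DataFrame({
            "probe": [f"p{i}" for i in range(200)],
            "chrom": rng.choice(["chr1", "chr2"], 200),
            "pos": rng.integers(1, 50_000, 200),
        })
        out = define_rsp_cpgs(snps, manifest, half_window=1000).set_index("probe")
        for _, row in manifest.iterrows():
            expected = any(
                s["chrom"] == row["chrom"] and abs(s["pos"] - row["pos"]) <= 1000
                for _, s in snps.iterrows()
            )
            assert out.loc[row["probe"], "rsp"] == expected


def _mv_table(values):
    vals = np.asarray(values, dtype=float)
    return pd.DataFrame({"probe": [f"p{i}" for i in range(len(vals))],
                         "mean": 0.5, "variance": vals**2, "mv": vals})


class TestBootstrap:
    def test_degenerate_identical_values_give_p_one(self):
        mv = _mv_table([0.3] * 8)
        res = bootstrap_mean_test(mv, ["p0", "p1"], B=200, seed=0)
        assert res.p_value == 1.0

    def test_size_one_subset_matches_enumeration(self):
        mv = _mv_table([0.1, 0.2, 0.3, 0.4, 0.5])
        res = bootstrap_mean_test(mv, ["p0"], B=10_000, seed=3)
        assert abs(res.p_value - 0.2) <= 0.02
        assert res.observed_mean == pytest.approx(0.1)

    def test_converges_to_exact_enumeration(self):
        rng = np.random.default_rng(4)
        values = rng.random(7)
        mv = _mv_table(values)
        rsp = ["p0", "p3", "p5"]
        observed = values[[0, 3, 5]].mean()
        exact = np.mean([
            np.mean(values[list(c)]) <= observed
            for c in combinations(range(7), 3)
        ])
        B = 10_000
        res = bootstrap_mean_test(mv, rsp, B=B, seed=5)
        tol = 3 * np.sqrt(exact * (1 - exact) / B) + 2 / B
        assert abs(res.p_value - exact) <= tol

    def test_seed_reproducibility_and_stability(self):
        rng = np.random.default_rng(6)
        mv = _mv_table(rng.random(40))
        a = bootstrap_mean_test(mv, ["p0", "p1", "p2"], B=2000, seed=1)
        b = bootstrap_mean_test(mv, ["p0", "p1", "p2"], B=2000, seed=1)
        c = bootstrap_mean_test(mv, ["p0", "p1", "p2"], B=2000, seed=2)
        assert a == b
        assert a.n_leq != c.n_leq or a.p_value == c.p_value
        assert abs(a.p_value - c.p_value) < 0.05

    def test_add_one_pvalue_identity(self):
        mv = _mv_table(np.linspace(0.01, 0.5, 20))
        res = bootstrap_mean_test(mv, ["p0", "p1"], B=500, seed=0)
        assert res.p_value == pytest.approx((res.n_leq + 1) / (res.n_resamples + 1))
        assert 0 < res.p_value <= 1

    def test_contract_violations(self):
        mv = _mv_table([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="proper subset"):
            bootstrap_mean_test(mv, [], B=200, seed=0)
        with pytest.raises(ValueError, match="proper subset"):
            bootstrap_mean_test(mv, ["p0", "p1", "p2"], B=200, seed=0)
        with pytest.raises(ValueError, match="at least 100"):
            bootstrap_mean_test(mv, ["p0"], B=10, seed=0)


class TestGerpComparison:
    def test_identical_groups(self):
        annotated = pd.DataFrame({"probe": list("abcdef"),
                                  "score": [1.0, 2, 3, 1, 2, 3]})
        rsp = pd.DataFrame({"probe": list("abcdef"),
                            "rsp": [True] * 3 + [False] * 3})
        res = gerp_compare_groups(annotated, rsp)
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_matches_hand_welch_formula(self):
        annotated = pd.DataFrame({"probe": list("abcdef"),
                                  "score": [1.0, 2, 3, 4, 5, 6]})
        rsp = pd.DataFrame({"probe": list("abcdef"),
                            "rsp": [True] * 3 + [False] * 3})
        res = gerp_compare_groups(annotated, rsp)
        # Welch t for {1,2,3} vs {4,5,6}: t = -3/sqrt(1/3+1/3)
        assert res["statistic"] == pytest.approx(-3 / np.sqrt(2 / 3))
        assert res["df"] == pytest.approx(4.0)

    def test_null_calibration_with_independent_plantings(self):
        rng = np.random.default_rng(12)
        n_reject = 0
        n_rep = 100
        for _ in range(n_rep):
            n = 150
            annotated = pd.DataFrame({"probe": [f"p{i}" for i in range(n)],
                                      "score": rng.normal(size=n)})
            rsp_flags = np.zeros(n, dtype=bool)
            rsp_flags[rng.choice(n, 15, replace=False)] = True
            rsp = pd.DataFrame({"probe": annotated["probe"], "rsp": rsp_flags})
            if gerp_compare_groups(annotated, rsp)["p_value"] < 0.05:
                n_reject += 1
        assert n_reject <= 10  # p > 0.05 in at least 90% of replicates

    def test_small_group_rejected(self):
        annotated = pd.DataFrame({"probe": list("abc"), "score": [1.0, 2, 3]})
        rsp = pd.DataFrame({"probe": list("abc"), "rsp": [True, False, False]})
        with pytest.raises(ValueError, match="at least 2"):
            gerp_compare_groups(annotated, rsp)
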