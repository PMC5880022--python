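"""Promoter mapping, gene ranking and the preranked enrichment statistic."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from methvar.enrichment import (
    enrichment_score,
    gene_mv,
    gsea_preranked,
    map_probes_to_promoters,
    significant_sets,
    zscore_rank,
)


def _annotation(tss_list):
    return pd.DataFrame(
        {"gene": [g for g, _ in tss_list], "chrom": "chr1",
         "tss": [t for _, t in tss_list], "strand": "+"}
    )


def _manifest(positions, chrom="chr1"):
    return pd.DataFrame(
        {"probe": [f"p{i}" for i in range(len(positions))],
         "chrom": chrom, "pos": positions}
    )


class TestPromoterMapping:
    def test_probe_at_tss_is_assigned(self):
        got = map_probes_to_promoters(_annotation([("G1", 5000)]), _manifest([5000]))
        assert list(got.itertuples(index=False)) == [("p0", "G1")]

    def test_probe_just_outside_flank_unassigned(self):
        got = map_probes_to_promoters(_annotation([("G1", 5000)]), _manifest([6501]))
        assert got.empty
        got = map_probes_to_promoters(_annotation([("G1", 5000)]), _manifest([6500]))
        assert len(got) == 1

    def test_probe_in_two_windows_assigned_to_both(self):
        ann = _annotation([("G1", 5000), ("G2", 6000)])
        got = map_probes_to_promoters(ann, _manifest([5500]))
        assert sorted(got["gene"]) == ["G1", "G2"]

    def test_matches_distance_oracle(self):
        rng = np.random.default_rng(21)
        ann = pd.DataFrame({
            "gene": [f"G{i}" for i in range(30)],
            "chrom": rng.choice(["chr1", "chr2"], 30),
            "tss": rng.integers(1, 60_000, 30),
            "strand": "+",
        })
        manifest = pd.DataFrame({
            "probe": [f"p{i}" for i in range(300)],
            "chrom": rng.choice(["chr1", "chr2"], 300),
            "pos": rng.integers(1, 60_000, 300),
        })
        got = set(map(tuple, map_probes_to_promoters(ann, manifest).to_numpy()))
        expected = {
            (p["probe"], g["gene"])
            for _, p in manifest.iterrows()
            for _, g in ann.iterrows()
            if p["chrom"] == g["chrom"] and abs(p["pos"] - g["tss"]) <= 1500
        }
        assert got == expected


class TestGeneMV:
    def _mv(self, pairs):
        return pd.DataFrame({"probe": [p for p, _ in pairs], "mean": 0.5,
                             "variance": 0.0, "mv": [v for _, v in pairs]})

    def test_single_probe_gene(self):
        assign = pd.DataFrame({"probe": ["p0"], "gene": ["G1"]})
        got, dropped = gene_mv(assign, self._mv([("p0", 0.07)]))
        assert got.loc[0, "X"] == pytest.approx(0.07)
        assert dropped == 0

    def test_mean_of_two_probes(self):
        assign = pd.DataFrame({"probe": ["p0", "p1"], "gene": ["G1", "G1"]})
        got, _ = gene_mv(assign, self._mv([("p0", 0.1), ("p1", 0.3)]))
        assert got.loc[0, "X"] == pytest.approx(0.2)
        assert got.loc[0, "n_probes"] == 2

    def test_shared_probe_contributes_to_both_genes(self):
        assign = pd.DataFrame({"probe": ["p0", "p0"], "gene": ["G1", "G2"]})
        got, _ = gene_mv(assign, self._mv([("p0", 0.4)]))
        assert sorted(got["gene"]) == ["G1", "G2"]
        assert (got["X"] == 0.4).all()

    def test_gene_with_no_surviving_probes_dropped(self):
        assign = pd.DataFrame({"probe": ["p0", "missing"], "gene": ["G1", "G2"]})
        got, dropped = gene_mv(assign, self._mv([("p0", 0.4)]))
        assert list(got["gene"]) == ["G1"]
        assert dropped == 1


class TestZscoreRank:
    def test_hand_computed_zscores(self):
        table = pd.DataFrame({"gene": ["a", "b", "c"], "X": [1.0, 2.0, 3.0],
                              "n_probes": 1})
        ranked = zscore_rank(table)
        assert list(ranked["gene"]) == ["c", "b", "a"]
        assert list(ranked["z"]) == pytest.approx([1.0, 0.0, -1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({"gene": [f"g{i}" for i in range(200)],
                              "X": rng.random(200), "n_probes": 1})
        z = zscore_rank(table)["z"].to_numpy()
        assert abs(z.mean()) <= 1e-10
        assert abs(z.std(ddof=1) - 1.0) <= 1e-10

    def test_ties_broken_alphabetically(self):
        table = pd.DataFrame({"gene": ["zz", "aa", "mm"], "X": [1.0, 1.0, 2.0],
                              "n_probes": 1})
        assert list(zscore_rank(table)["gene"]) == ["mm", "aa", "zz"]

    def test_degenerate_identical_values(self):
        table = pd.DataFrame({"gene": ["a", "b"], "X": [1.0, 1.0], "n_probes": 1})
        with pytest.raises(ValueError, match="identical"):
            zscore_rank(table)


TOY_SCORES = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
TOY_GENES = ["g1", "g2", "g3", "g4", "g5", "g6"]


def _plain_running_sum_es(hit_positions, scores):
    """Independent plain-Python running-sum implementation."""
    n = len(scores)
    hits = set(hit_positions)
    total = sum(abs(scores[i]) for i in hits)
    misses = n - len(hits)
    run, best = 0.0, 0.0
    for i in range(n):
        run += abs(scores[i]) / total if i in hits else -1.0 / misses
        if abs(run) > abs(best):
            best = run
    return best


class TestEnrichmentScore:
    def test_top_two_set_reaches_full_deviation(self):
        mask = np.array([True, True, False, False, False, False])
        es, peak = enrichment_score(mask, TOY_SCORES, weight=1.0)
        assert es == pytest.approx(1.0)
        assert peak == 1

    def test_matches_plain_enumeration_on_random_sets(self):
        rng = np.random.default_rng(7)
        scores = np.sort(rng.normal(size=25))[::-1]
        for _ in range(50):
            k = int(rng.integers(2, 10))
            idx = rng.choice(25, k, replace=False)
            mask = np.zeros(25, dtype=bool)
            mask[idx] = True
            es, _ = enrichment_score(mask, scores)
            assert es == pytest.approx(_plain_running_sum_es(idx, scores))
            assert -1.0 <= es <= 1.0

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(8)
        scores = np.sort(rng.normal(size=20))[::-1]
        mask = np.zeros(20, dtype=bool)
        mask[rng.choice(20, 5, replace=False)] = True
        es, _ = enrichment_score(mask, scores)
        es_flipped, _ = enrichment_score(mask[::-1], -scores[::-1])
        assert es_flipped == pytest.approx(-es)

    def test_matches_gseapy_reference(self):
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(3)
        genes = [f"G{i:02d}" for i in range(30)]
        z = np.sort(rng.normal(size=30))[::-1]
        sets = {"SA": genes[:5], "SB": genes[10:18], "SC": genes[-6:]}
        res = gseapy.prerank(
            rnk=pd.Series(z, index=genes), gene_sets=sets, permutation_num=5,
            min_size=3, max_size=500, weight=1.0, seed=1, no_plot=True,
            outdir=None,
        ).res2d.set_index("Term")
        for name, members in sets.items():
            mask = np.isin(genes, members)
            es, _ = enrichment_score(mask, z, 1.0)
            assert es == pytest.approx(float(res.loc[name, "ES"]), abs=1e-9)


class TestGseaPreranked:
    def _ranked(self):
        return pd.DataFrame({"gene": TOY_GENES, "z": TOY_SCORES})

    def test_exhaustive_p_matches_subset_enumeration(self):
        results = gsea_preranked(self._ranked(), {"top2": ["g1", "g2"]},
                                 n_perm=0, min_size=2, exhaustive=True)
        r = results[0]
        assert r.es == pytest.approx(1.0)
        null = [
            _plain_running_sum_es(c, TOY_SCORES)
            for c in combinations(range(6), 2)
        ]
        same_sign = [e for e in null if e >= 0]
        expected_p = sum(e >= 1.0 - 1e-12 for e in same_sign) / len(same_sign)
        assert r.p_value == pytest.approx(expected_p)
        assert r.direction == "high-MV tail"
        assert r.leading_edge == ("g1", "g2")

    def test_whole_list_set_is_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            results = gsea_preranked(self._ranked(), {"all": TOY_GENES},
                                     n_perm=10, min_size=2)
        assert results == []

    def test_no_overlap_set_is_skipped(self):
        with pytest.warns(UserWarning, match="no overlap"):
            results = gsea_preranked(self._ranked(), {"none": ["zz"]}, n_perm=10)
        assert results == []

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(50)]
        ranked = pd.DataFrame({"gene": genes,
                               "z": np.sort(rng.normal(size=50))[::-1]})
        sets = {"s1": genes[:8], "s2": genes[20:30]}
        a = gsea_preranked(ranked, sets, n_perm=200, seed=4)
        b = gsea_preranked(ranked, sets, n_perm=200, seed=4)
        assert a == b


class TestSignificantSets:
    def test_joint_thresholds(self):
        from methvar.enrichment import EnrichmentResult

        def res(name, p, q, es=0.5):
            return EnrichmentResult(name, 5, es, es * 2, p, q,
                                    "high-MV tail" if es >= 0 else "low-MV tail",
                                    ())

        results = [res("keep", 0.005, 0.1), res("bad_q", 0.005, 0.3),
                   res("bad_p", 0.02, 0.1), res("neg", 0.001, 0.05, es=-0.4)]
        sig = significant_sets(results)
        assert [r.name for r in sig["high"]] == ["keep"]
        assert [r.name for r in sig["low"]] == ["neg"]
        assert significant_sets([]) == {"high": [], "low": []}
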