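"""Normalisation, single-sample scores, NC-FC, recurrence, GSEA, ORA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ramscape import transcriptome as tx


class TestLog2Cpm:
    def test_single_dominant_gene_limit(self):
        # one gene holds (almost) the whole library: log2CPM -> log2(1e6)
        counts = pd.DataFrame({"s": [10_000_000, 0]}, index=["g1", "g2"])
        out = tx.normalize_log2cpm(counts)
        assert out.loc["g1", "s"] == pytest.approx(math.log2(1e6), abs=0.01)

    def test_depth_scale_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 1000, 50)
        counts = pd.DataFrame({"a": base, "b": base * 2})
        cpm = tx.cpm(counts, pseudocount=0.0)
        assert np.allclose(cpm["a"], cpm["b"], rtol=1e-3)

    def test_zero_counts_finite(self):
        counts = pd.DataFrame({"s": [0, 100]}, index=["g1", "g2"])
        assert np.isfinite(tx.normalize_log2cpm(counts)).all().all()

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            tx.cpm(pd.DataFrame({"s": [0, 0]}))


class TestSsScore:
    def _sample(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)])

    def test_top_ranked_set_is_maximal(self):
        s = self._sample()
        top = list(s.sort_values(ascending=False).index[:10])
        score_top = tx.ss_enrichment_score(s, top)
        others = [tx.ss_enrichment_score(s, list(np.random.default_rng(i)
                  .choice(s.index, 10, replace=False))) for i in range(20)]
        assert score_top >= max(others)
        assert score_top > 0.8

    def test_uniformly_spread_set_near_zero(self):
        n = 400
        s = pd.Series(np.arange(n, dtype=float), index=[f"g{i:03d}" for i in range(n)])
        spread = [f"g{i:03d}" for i in range(0, n, 40)]
        assert abs(tx.ss_enrichment_score(s, spread)) < 0.15

    def test_upshift_of_set_genes_increases_score(self):
        s = self._sample()
        genes = list(s.index[:10])
        before = tx.ss_enrichment_score(s, genes)
        s2 = s.copy()
        s2[genes] += 2.0
        assert tx.ss_enrichment_score(s2, genes) > before

    def test_monotone_transform_invariance(self):
        s = self._sample(seed=3)
        genes = list(s.index[5:20])
        assert tx.ss_enrichment_score(np.exp(s), genes) == pytest.approx(
            tx.ss_enrichment_score(s, genes))

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            tx.ss_enrichment_score(self._sample(), ["absent"])


class TestNcFc:
    def _series(self, vals):
        return pd.Series(vals, index=[f"g{i}" for i in range(len(vals))], dtype=float)

    def test_directions(self):
        # gene0: FC_T 8 / FC_N 2 -> NC 4 (up); gene1: 2/2 -> 1 (none);
        # gene2: 0.2/1 -> 0.2 (down)
        ta = self._series([8, 2, 0.2])
        tb = self._series([1, 1, 1])
        na = self._series([2, 2, 1])
        nb = self._series([1, 1, 1])
        out = tx.nc_fc(ta, tb, na, nb)
        assert list(out["direction"]) == ["up", "none", "down"]
        assert out["nc_fc"].iloc[0] == pytest.approx(4.0)

    def test_contamination_only_gene_removed(self):
        # organ-normal marker: differs in normals exactly as in tumors
        ta, tb = self._series([50, 1]), self._series([1, 1])
        na, nb = self._series([50, 1]), self._series([1, 1])
        out = tx.nc_fc(ta, tb, na, nb)
        assert out["direction"].iloc[0] == "none"
        assert out["nc_fc"].iloc[0] == pytest.approx(1.0)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            tx.nc_fc(self._series([1]), self._series([1]),
                     pd.Series({"other": 1.0}), self._series([1]))


class TestRecurrence:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["comparison_id", "case", "organ",
                                           "gene", "direction"])

    def test_thresholds_met(self):
        rows = [(f"c{i}", f"P{min(i, 2)}", "liver", "G1", "up") for i in range(4)]
        rows += [(f"c{i}", "P9", "liver", "other", "down") for i in range(4, 10)]
        out = tx.nc_deg_recurrence(self._calls(rows), 0.30, 3)
        got = out[out.gene == "G1"]
        assert len(got) == 1  # 4/10 comparisons >= 30%, 3 cases
        assert got["recurrence"].iloc[0] == pytest.approx(0.4)

    def test_too_few_cases(self):
        rows = [(f"c{i}", f"P{i % 2}", "liver", "G1", "up") for i in range(3)]
        rows += [(f"c{i}", "P9", "liver", "other", "down") for i in range(3, 10)]
        out = tx.nc_deg_recurrence(self._calls(rows), 0.30, 3)
        assert out[out.gene == "G1"].empty

    def test_opposite_directions_never_merge(self):
        rows = [(f"c{i}", f"P{i}", "liver", "G1", "up") for i in range(2)]
        rows += [(f"c{i}", f"P{i}", "liver", "G1", "down") for i in range(2, 4)]
        out = tx.nc_deg_recurrence(self._calls(rows), 0.30, 3)
        assert out.empty


class TestGsea:
    def _ranking(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)])

    def test_top_loaded_set_extreme(self):
        r = self._ranking()
        top = list(r.sort_values(ascending=False).index[:15])
        res = tx.preranked_gsea(r, top, n_perm=200, seed=1)
        assert res["es"] > 0.9
        assert res["p"] <= 1 / 50  # smallest achievable sign-conditioned p

    def test_sign_flips_under_negated_ranking(self):
        r = self._ranking(seed=2)
        genes = list(r.index[:20])
        a = tx.preranked_gsea(r, genes, n_perm=100, seed=1)
        b = tx.preranked_gsea(-r, genes, n_perm=100, seed=1)
        assert np.sign(a["es"]) == -np.sign(b["es"])

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            tx.preranked_gsea(self._ranking(), ["missing"], n_perm=100)

    def test_null_p_values_roughly_uniform(self):
        """Permutation p under random rankings/sets is uniform (KS test)."""
        from scipy import stats
        ps = []
        rng = np.random.default_rng(7)
        for i in range(60):
            r = self._ranking(n=120, seed=1000 + i)
            genes = list(rng.choice(r.index, 12, replace=False))
            ps.append(tx.preranked_gsea(r, genes, n_perm=200, seed=i)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestNcDgs:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["set", "nes"])

    def test_tumor_only_kept(self):
        out = tx.nc_dgs(self._df([("A", 2.0)]), self._df([("B", 2.0)]))
        assert list(out["set"]) == ["A"]

    def test_same_sign_removed(self):
        out = tx.nc_dgs(self._df([("A", 2.0)]), self._df([("A", 1.5)]))
        assert out.empty

    def test_opposite_sign_kept(self):
        out = tx.nc_dgs(self._df([("A", 2.0)]), self._df([("A", -1.5)]))
        assert list(out["set"]) == ["A"]


class TestOra:
    def test_full_set_ranks_first(self):
        universe = [f"g{i}" for i in range(30)]
        sets = {"hit": universe[:5], "miss": universe[10:20]}
        out = tx.ora_test(universe[:5], sets, universe)
        assert out["set"].iloc[0] == "hit"

    def test_matches_enumeration_small_universe(self):
        universe = [f"g{i}" for i in range(12)]
        gene_list = set(universe[:4])
        anno = set(universe[2:8])
        k_obs = len(gene_list & anno)
        total = math.comb(12, 4)
        p_exp = sum(1 for combo in itertools.combinations(universe, 4)
                    if len(set(combo) & anno) >= k_obs) / total
        out = tx.ora_test(gene_list, {"s": list(anno)}, universe)
        assert out["p"].iloc[0] == pytest.approx(p_exp, abs=1e-12)

    def test_fdr_never_below_raw_p(self):
        universe = [f"g{i}" for i in range(40)]
        sets = {f"s{i}": universe[i:i + 8] for i in range(10)}
        out = tx.ora_test(universe[:6], sets, universe)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestOrganSignatures:
    def test_implanted_markers_recovered(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:03d}" for i in range(60)]
        organs = ["brain"] * 6 + ["liver"] * 6
        counts = pd.DataFrame(rng.poisson(100, (60, 12)), index=genes,
                              columns=[f"s{i}" for i in range(12)])
        counts.iloc[:5, :6] *= 16    # brain markers
        counts.iloc[5:10, 6:] *= 16  # liver markers
        log2cpm = tx.normalize_log2cpm(counts)
        organ_of = pd.Series(organs, index=counts.columns)
        sigs = tx.organ_normal_signatures(log2cpm, organ_of)
        assert set(sigs["brain"]) == set(genes[:5])
        assert set(sigs["liver"]) == set(genes[5:10])

    def test_identical_profiles_give_empty_sets(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i:03d}" for i in range(40)]
        counts = pd.DataFrame(rng.poisson(100, (40, 8)), index=genes,
                              columns=[f"s{i}" for i in range(8)])
        organ_of = pd.Series(["a"] * 4 + ["b"] * 4, index=counts.columns)
        sigs = tx.organ_normal_signatures(tx.normalize_log2cpm(counts), organ_of)
        assert all(len(v) == 0 for v in sigs.values())
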