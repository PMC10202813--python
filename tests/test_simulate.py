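"""Ground-truth fidelity and determinism of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from ramscape import phylo
from ramscape.io import write_cohort
from ramscape.signatures import build_sbs96_spectrum
from ramscape.simulate import (SimulationConfig, make_reference_catalogs,
                               make_rs_catalog, make_signature_catalog,
                               simulate_cohort)


class TestCatalogs:
    def test_orthogonal_signatures_have_zero_cosine(self):
        cat = make_signature_catalog(names=["a", "b", "c"], orthogonal=True, seed=1)
        P = cat.profiles.to_numpy()
        gram = P.T @ P
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0)

    def test_columns_sum_to_one(self):
        for cat in (make_signature_catalog(seed=2), make_rs_catalog(seed=2)):
            assert np.allclose(cat.profiles.sum(axis=0), 1.0)

    def test_seeded_regeneration_identical(self):
        a = make_signature_catalog(seed=9).profiles
        b = make_signature_catalog(seed=9).profiles
        pd.testing.assert_frame_equal(a, b)

    def test_too_many_orthogonal_signatures_rejected(self):
        with pytest.raises(ValueError, match="orthogonal"):
            make_signature_catalog(names=[f"s{i}" for i in range(97)],
                                   orthogonal=True)

    def test_rs2_like_mass_on_large_nonclustered(self):
        cat = make_rs_catalog(seed=0)
        col = cat.profiles["RS2-like"]
        large = [c for c in col.index if c.startswith("non-clustered")
                 and ("100kb-1Mb" in c or "1-10Mb" in c or ">10Mb" in c
                      or c.endswith("tra"))]
        assert col[large].sum() == pytest.approx(1.0)


class TestDeterminism:
    def test_identical_seed_identical_bundle(self, small_config, tmp_path):
        b1, t1 = simulate_cohort(small_config)
        b2, t2 = simulate_cohort(small_config)
        write_cohort(b1, tmp_path / "a")
        write_cohort(b2, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
        assert t1 == t2

    def test_different_seed_differs(self, small_config):
        import dataclasses
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        b1, _ = simulate_cohort(small_config)
        b2, _ = simulate_cohort(other)
        assert not b1.mutations.equals(b2.mutations)


class TestMutationTruth:
    def test_degenerate_late_mixture_draws_from_one_signature(self):
        cat = make_signature_catalog(seed=3)
        exposures = {
            arm: {"early": {"SBS-UV1": 1.0}, "intermediate": {"SBS-UV1": 1.0},
                  "late": {"SBS-HRD": 1.0}}
            for arm in ("MAPKi", "ICB", "MAPKi+ICB")}
        cfg = SimulationConfig(seed=4, n_cases=2, tier_exposures=exposures,
                               tier_mutation_counts={"early": 50,
                                                     "intermediate": 30,
                                                     "late": 2000},
                               n_naive=10, n_genes=200)
        bundle, truth = simulate_cohort(cfg, catalog=cat)
        late_ids = {m for m, t in truth["tiers"].items() if t == "late"}
        late = bundle.mutations[bundle.mutations.mutation_id.isin(late_ids)]
        spec = build_sbs96_spectrum(late.drop_duplicates("mutation_id"))
        emp = spec.counts / spec.total
        ref = cat.profiles["SBS-HRD"].to_numpy()
        assert 0.5 * np.abs(emp - ref).sum() < 0.05  # total variation
        # channels outside the signature's support never drawn
        assert np.all(spec.counts[ref == 0] == 0)

    def test_two_tumor_cases_have_no_intermediate_truth(self):
        cfg = SimulationConfig(seed=5, n_cases=2, organs_per_case=2,
                               tumors_per_organ=1, n_naive=10, n_genes=200,
                               tier_mutation_counts={"early": 40,
                                                     "intermediate": 40,
                                                     "late": 40})
        bundle, truth = simulate_cohort(cfg)
        assert "intermediate" not in set(truth["tiers"].values())

    def test_single_signature_channel_frequencies_match_profile(self):
        """50,000 draws from one signature match its profile in TV distance."""
        cat = make_signature_catalog(seed=6)
        rng = np.random.default_rng(0)
        p = cat.profiles["SBS-UV1"].to_numpy()
        draws = rng.multinomial(50_000, p)
        tv = 0.5 * np.abs(draws / 50_000 - p).sum()
        assert tv <= 0.02

    def test_mean_vaf_strictly_decreasing_by_tier(self, small_cohort):
        bundle, truth = small_cohort
        muts = bundle.mutations.copy()
        muts["tier"] = muts["mutation_id"].map(truth["tiers"])
        muts["vaf"] = muts["t_alt_reads"] / muts["t_depth"]
        means = muts.groupby("tier")["vaf"].mean()
        assert means["early"] > means["intermediate"] > means["late"]

    def test_truth_tiers_match_emitted_sharing_pattern(self, small_cohort):
        bundle, truth = small_cohort
        for case in sorted(bundle.manifest.case_id.unique()):
            tumors = bundle.tumors_of_case(case)
            muts = bundle.mutations[bundle.mutations.case == case]
            carriers = muts.groupby("mutation_id")["sample"].nunique()
            for mid, k in carriers.items():
                expected = ("early" if k == len(tumors)
                            else "late" if k == 1 else "intermediate")
                assert truth["tiers"][mid] == expected


class TestExpressionTruth:
    def test_an_tumor_fraction_at_most_ten_percent(self, small_cohort):
        _, truth = small_cohort
        fractions = list(truth["an_tumor_fraction"].values())
        assert fractions and max(fractions) <= 0.10

    def test_invalid_exposure_mixture_rejected(self):
        cfg = SimulationConfig(
            seed=1, tier_exposures={"MAPKi": {"early": {"NOT-A-SIG": 1.0}}})
        with pytest.raises(ValueError, match="unknown signatures"):
            simulate_cohort(cfg)

    def test_mixture_not_summing_to_one_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            SimulationConfig(tier_exposures={
                "MAPKi": {"early": {"SBS-UV1": 0.5}}})

    def test_reference_catalog_bundle(self, small_config):
        cat, sets = make_reference_catalogs(small_config)
        assert cat.space == "SBS96"
        assert any(k.startswith("archetype_") for k in sets)
        assert any(k.startswith("marker_") for k in sets)


class TestTreeTruth:
    def test_noiseless_topology_recovery(self, small_cohort):
        """Inferred parsimony trees reproduce the generating clone trees."""
        bundle, truth = small_cohort
        for case in sorted(bundle.manifest.case_id.unique()):
            tumors = bundle.tumors_of_case(case)
            muts = bundle.mutations[bundle.mutations.case == case]
            mat = phylo.build_presence_matrix(muts, tumors, min_alt_reads=1)
            tree = phylo.infer_parsimony_tree(mat, seed=0)
            assert _clade_set(tree.newick) == _clade_set(truth["trees"][case])


def _clade_set(newick):
    """Nested clades of a newick string (ignoring rotation), as frozensets."""
    clades = set()

    def parse(s, i):
        leaves = []
        assert s[i] == "("
        i += 1
        while s[i] != ")":
            if s[i] == "(":
                sub, i = parse(s, i)
                leaves.extend(sub)
            else:
                j = i
                while s[j] not in ",()":
                    j += 1
                leaves.append(s[i:j])
                i = j
            if s[i] == ",":
                i += 1
        clades.add(frozenset(leaves))
        return leaves, i + 1

    parse(newick, 0)
    return {c for c in clades if len(c) > 1}
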