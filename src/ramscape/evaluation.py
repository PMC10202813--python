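"""Recovery metrics against simulator ground truth.

These helpers run the analysis paths on simulated cohorts and score them
against the generator's truth records: temporal-tier label accuracy,
repair-mechanism confusion, signature-exposure recovery, normal-corrected
DEG precision/recall with contamination exclusion, and the power/size of the
cohort CNA enrichment rules. They are used by the validation drivers and the
acceptance checks; none of them contain independent oracles (those live with
the tests that use them).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ramscape import phylo, selection, sv
from ramscape import transcriptome as tx
from ramscape.rng import substream
from ramscape.signatures import Spectrum, refit_exposures
from ramscape.simulate import (ORGANS, SimulationConfig, make_signature_catalog,
                               simulate_cohort)


def tier_label_accuracy(bundle, truth, min_alt_reads: int = 3) -> float:
    """Fraction of mutations whose sharing-pattern tier matches truth."""
    correct = total = 0
    for case in sorted(bundle.manifest.case_id.unique()):
        tumors = bundle.tumors_of_case(case)
        muts = bundle.mutations[bundle.mutations.case == case]
        matrix = phylo.build_presence_matrix(muts, tumors,
                                             min_alt_reads=min_alt_reads)
        tiers = phylo.tier_events(matrix)
        emitted = set(muts["mutation_id"])
        for mid in emitted:
            total += 1
            got = tiers.get(mid)
            if got is not None and got == truth["tiers"][mid]:
                correct += 1
    return correct / total if total else float("nan")


def tier_mean_vafs(bundle, truth) -> dict[str, float]:
    muts = bundle.mutations.copy()
    muts["tier"] = muts["mutation_id"].map(truth["tiers"])
    muts["vaf"] = muts["t_alt_reads"] / muts["t_depth"].clip(lower=1)
    return muts.groupby("tier")["vaf"].mean().to_dict()


def repair_confusion(bundle, truth) -> pd.DataFrame:
    """Truth mechanism x inferred mechanism counts over distinct SVs."""
    fam = bundle.svs.drop_duplicates("name")
    rows = []
    for r in fam.itertuples(index=False):
        rows.append({"truth": truth["repair"][r.name],
                     "inferred": sv.classify_junction(int(r.homlen))})
    df = pd.DataFrame(rows)
    order = ["NHEJ", "alt-NHEJ", "HRR"]
    return (df.groupby(["truth", "inferred"]).size().unstack(fill_value=0)
            .reindex(index=order, columns=order, fill_value=0))


def signature_recovery_errors(n_trials: int = 200, n_draws: int = 2000,
                              seed: int = 0) -> np.ndarray:
    """L1 exposure-recovery errors for random 3-signature mixtures of a
    well-conditioned (orthogonal) catalog."""
    cat = make_signature_catalog(names=[f"S{i}" for i in range(1, 6)],
                                 orthogonal=True, seed=seed)
    rng = substream(seed, "signature-recovery")
    P = cat.profiles.to_numpy()
    errs = np.empty(n_trials)
    for i in range(n_trials):
        idx = rng.choice(P.shape[1], size=3, replace=False)
        e = np.zeros(P.shape[1])
        e[idx] = rng.dirichlet(np.ones(3) * 2)
        draws = rng.multinomial(n_draws, P @ e).astype(float)
        exp = refit_exposures(Spectrum("SBS96", draws), cat, prune_cutoff=0.0)
        errs[i] = np.abs(exp.proportions.to_numpy() - e).sum()
    return errs


def _rna_config(seed: int) -> SimulationConfig:
    # RNA-focused cohort isolating the normal-correction mechanism: organ
    # markers are the contamination-only genes, the immune background is
    # uniform across samples, and two organs per case keep any given organ
    # pair from co-occurring often enough to let the inverse-correction
    # artifact (other-organ markers called up) reach the recurrence bar.
    uniform = {"archetype_01": 1.0}
    return SimulationConfig(
        seed=seed, n_cases=12, organs_per_case=2, tumors_per_organ=1,
        tier_mutation_counts={"early": 20, "intermediate": 10, "late": 10},
        sv_tier_counts={"early": 5, "intermediate": 0, "late": 5},
        indels_per_tumor=2, n_naive=10, n_mapki_pairs=2, n_icb_pairs=2,
        n_genes=1200,
        archetype_mix={"tumor": uniform, "AN": uniform, "NAN": uniform},
    )


def nc_deg_metrics(seed: int, min_fraction: float = 0.30,
                   min_cases: int = 3) -> dict:
    """Precision/recall of recurrent up NC-DEGs against implanted organ
    programs, plus the exclusion rate of pure-contamination (organ-marker)
    genes from the up lists."""
    cfg = _rna_config(seed)
    bundle, truth = simulate_cohort(cfg)
    m = bundle.manifest.set_index("sample_id")
    cpm = tx.cpm(bundle.expression)
    calls = []
    nans = bundle.manifest[bundle.manifest.compartment == "NAN"]
    for case in sorted(bundle.manifest.case_id.unique()):
        sub = bundle.manifest[bundle.manifest.case_id == case]
        tum = sub[sub.compartment == "tumor"]
        nan_of = sub[sub.compartment == "NAN"].set_index("organ")["sample_id"]
        for ta in tum.itertuples(index=False):
            for tb in tum.itertuples(index=False):
                if ta.organ == tb.organ:
                    continue
                rec = tx.nc_fc(cpm[ta.sample_id], cpm[tb.sample_id],
                               cpm[nan_of[ta.organ]], cpm[nan_of[tb.organ]])
                hit = rec[rec.direction != "none"]
                for gene, r in hit.iterrows():
                    calls.append({"comparison_id": f"{ta.sample_id}|{tb.sample_id}",
                                  "case": case, "organ": ta.organ,
                                  "gene": gene, "direction": r["direction"]})
    calls_df = pd.DataFrame(calls, columns=["comparison_id", "case", "organ",
                                            "gene", "direction"])
    recurrent = tx.nc_deg_recurrence(calls_df, min_fraction=min_fraction,
                                     min_cases=min_cases)
    up = recurrent[recurrent.direction == "up"]
    # eligible organs: enough cases to clear the min_cases rule at all
    organ_cases = (bundle.manifest[bundle.manifest.compartment == "tumor"]
                   .groupby("organ")["case_id"].nunique())
    eligible = set(organ_cases.index[organ_cases >= min_cases])
    lig = {p["ligand"] for p in truth["lr_pairs"]}
    tp = fp = fn = 0
    for organ in eligible:
        implanted = set(truth["organ_programs"][organ])
        if organ == "liver":
            implanted |= lig  # ligand genes ride on the liver tumor program
        called = set(up[up.organ == organ]["gene"])
        tp += len(called & implanted)
        fp += len(called - implanted)
        fn += len(implanted - called)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    markers = {g for organ in ORGANS
               for g in bundle.gene_sets[f"marker_{organ}"]}
    up_genes = set(up["gene"])
    excluded = 1.0 - len(markers & up_genes) / len(markers)
    return {"precision": precision, "recall": recall,
            "contamination_excluded": excluded}


def cna_enrichment_replicate(seed: int, n_a: int = 12, n_b: int = 300,
                             freq_implant: float = 0.6,
                             freq_base: float = 0.1,
                             n_implant: int = 10, n_null: int = 30,
                             alpha: float = 0.05) -> dict:
    """One power/size replicate of the patient-level Fisher enrichment rule.

    Patient-level amplification calls are drawn per gene: implanted genes at
    ``freq_implant`` in cohort A vs ``freq_base`` in B, null genes at
    ``freq_base`` in both. Returns the implanted-gene flag rate (power) and
    the null false-flag rate at BH ``alpha``.
    """
    rng = substream(seed, "cna-power")
    genes = [f"IMP{i}" for i in range(n_implant)] + [f"NUL{i}" for i in range(n_null)]
    rows_a, rows_b = [], []
    for g in genes:
        pa = freq_implant if g.startswith("IMP") else freq_base
        for j, hit in enumerate(rng.random(n_a) < pa):
            rows_a.append({"gene": g, "sample": f"a{j}", "case": f"a{j}",
                           "call": "amp" if hit else "neutral", "total_cn": 4 if hit else 2})
        for j, hit in enumerate(rng.random(n_b) < freq_base):
            rows_b.append({"gene": g, "sample": f"b{j}", "case": f"b{j}",
                           "call": "amp" if hit else "neutral", "total_cn": 4 if hit else 2})
    ta = selection.build_patient_event_table(pd.DataFrame(rows_a), "amp")
    tb = selection.build_patient_event_table(pd.DataFrame(rows_b), "amp")
    out = selection.fisher_cna_enrichment(ta, tb, alpha=alpha).set_index("gene")
    power = out.loc[[g for g in genes if g.startswith("IMP")], "enriched"].mean()
    fp = out.loc[[g for g in genes if g.startswith("NUL")], "enriched"].mean()
    return {"power": float(power), "false_flag_rate": float(fp)}


def gsea_null_pvalues(n_trials: int = 200, n_genes: int = 150,
                      set_size: int = 12, n_perm: int = 300,
                      seed: int = 0) -> np.ndarray:
    """Permutation p-values for random sets under random rankings."""
    rng = substream(seed, "gsea-null")
    ps = np.empty(n_trials)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    for i in range(n_trials):
        ranking = pd.Series(rng.normal(size=n_genes), index=genes)
        gene_set = list(rng.choice(genes, size=set_size, replace=False))
        res = tx.preranked_gsea(ranking, gene_set, n_perm=n_perm,
                                seed=int(rng.integers(2 ** 31)))
        ps[i] = res["p"]
    return ps


def tier_recovery_study(n_seeds: int = 20, depth: float = 200.0,
                        noiseless_depth: float = 20000.0,
                        base_seed: int = 0) -> dict:
    """Tier-label recovery at high depth (effectively noiseless) and at the
    study's read depth, plus the early-vs-late VAF ordering per cohort."""
    def cfg(seed, d):
        return SimulationConfig(
            seed=seed, n_cases=2, organs_per_case=3, tumors_per_organ=1,
            depth=d,
            tier_mutation_counts={"early": 60, "intermediate": 30, "late": 30},
            sv_tier_counts={"early": 5, "intermediate": 0, "late": 5},
            indels_per_tumor=2, n_naive=5, n_mapki_pairs=2, n_icb_pairs=2,
            n_genes=60)

    noiseless_acc, noisy_acc, vaf_ordered = [], [], []
    for s in range(n_seeds):
        b0, t0 = simulate_cohort(cfg(base_seed + s, noiseless_depth))
        noiseless_acc.append(tier_label_accuracy(b0, t0))
        b1, t1 = simulate_cohort(cfg(base_seed + 1000 + s, depth))
        noisy_acc.append(tier_label_accuracy(b1, t1))
        vafs = tier_mean_vafs(b1, t1)
        vaf_ordered.append(vafs["early"] > vafs["late"])
    return {
        "noiseless_accuracy": float(np.mean(noiseless_acc)),
        "noisy_accuracy": float(np.mean(noisy_acc)),
        "vaf_ordering_fraction": float(np.mean(vaf_ordered)),
    }
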