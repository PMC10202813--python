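"""End-to-end orchestration of the cohort analysis stages.

``run_pipeline`` chains the stages — temporal tiering and per-case parsimony
trees, per-tier signature refitting, rearrangement classification and
repair-mechanism inference, copy-number enrichment, clonality/organ
preference, normal-corrected transcriptomics and immune-archetype
composition — into one JSON-serialisable report. All thresholds live in
``PipelineConfig`` with the study's defaults; the report embeds the resolved
configuration and is byte-identical for identical (config, seed).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ramscape import clonality, immune, phylo, selection, signatures, sv
from ramscape import transcriptome as tx
from ramscape.io import CohortBundle
from ramscape.simulate import (SimulationConfig, make_reference_catalogs,
                               make_rs_catalog, simulate_cohort)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, named once."""

    nc_fc_up: float = 2.0
    nc_fc_down: float = 0.5
    nc_recurrence: float = 0.30
    nc_min_cases: int = 3
    delta_ccf: float = 0.2
    organ_min_patients: int = 3
    clonal_cutoff: float = 0.8
    homology_bins: tuple = (1, 6)
    sv_recurrence_fraction: float = 0.5
    translocation_min_tumors: int = 4
    bh_alpha: float = 0.05
    n_perm: int = 1000
    presence_min_alt_reads: int = 3
    signature_prune_cutoff: float = 0.06
    signature_cosine_tolerance: float = 0.01
    run_dna: bool = True
    run_rna: bool = True
    seed: int = 0


def run_pipeline(pipe: PipelineConfig | None = None,
                 sim: SimulationConfig | None = None,
                 bundle: CohortBundle | None = None) -> dict:
    """Run all enabled stages on ``bundle`` (simulated when omitted)."""
    pipe = pipe or PipelineConfig()
    if bundle is None:
        sim = sim or SimulationConfig(seed=pipe.seed)
        bundle, _ = simulate_cohort(sim)
    else:
        sim = sim or SimulationConfig(seed=pipe.seed)
    catalog, gene_sets = make_reference_catalogs(sim)
    if bundle.gene_sets:
        gene_sets = bundle.gene_sets
    report = {"config": dataclasses.asdict(pipe)}
    report["config"]["homology_bins"] = list(pipe.homology_bins)

    if pipe.run_dna:
        report["phylogeny"] = _stage_phylo(bundle, pipe)
        report["signatures"] = _stage_signatures(bundle, pipe, catalog,
                                                 report["phylogeny"])
        report["sv"] = _stage_sv(bundle, pipe)
        report["cna"] = _stage_cna(bundle, pipe)
        report["clonality"] = _stage_clonality(bundle, pipe)
    if pipe.run_rna and bundle.expression is not None:
        report["transcriptome"] = _stage_transcriptome(bundle, pipe, gene_sets)
        report["immune"] = _stage_immune(bundle, pipe, gene_sets)
    return report


def report_json(report: dict) -> str:
    return json.dumps(report, indent=1, sort_keys=True, default=_jsonify)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def _multi_tumor_cases(bundle) -> list[str]:
    m = bundle.manifest
    counts = m[m.compartment == "tumor"].groupby("case_id").size()
    return sorted(counts.index[counts >= 2])


def _stage_phylo(bundle, pipe) -> dict:
    out = {"cases": {}}
    for case in _multi_tumor_cases(bundle):
        tumors = bundle.tumors_of_case(case)
        muts = bundle.mutations[bundle.mutations.case == case]
        matrix = phylo.build_presence_matrix(muts, tumors,
                                             min_alt_reads=pipe.presence_min_alt_reads)
        tiers = phylo.tier_events(matrix)
        tree = phylo.infer_parsimony_tree(matrix, seed=pipe.seed)
        out["cases"][case] = {
            "newick": tree.newick,
            "parsimony_score": tree.score,
            "tier_counts": tiers.value_counts().to_dict(),
            "tiers": tiers.to_dict(),
        }
    return out


def _stage_signatures(bundle, pipe, catalog, phylo_report) -> dict:
    tables = []
    for case, info in phylo_report["cases"].items():
        tiers = pd.Series(info["tiers"])
        muts = bundle.mutations[bundle.mutations.case == case]
        tab = signatures.per_tier_signatures(
            muts, tiers, catalog, case=case,
            prune_cutoff=pipe.signature_prune_cutoff,
            cosine_tolerance=pipe.signature_cosine_tolerance)
        tables.append(tab)
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    # mean VAF per tier across the cohort (tier ordering sanity statistic)
    vafs = {}
    for case, info in phylo_report["cases"].items():
        muts = bundle.mutations[bundle.mutations.case == case].copy()
        muts["tier"] = muts["mutation_id"].map(info["tiers"])
        muts["vaf"] = muts["t_alt_reads"] / muts["t_depth"].clip(lower=1)
        carried = muts[muts["t_alt_reads"] >= pipe.presence_min_alt_reads]
        for tier, sub in carried.groupby("tier"):
            vafs.setdefault(tier, []).extend(sub["vaf"].tolist())
    mean_vaf = {t: float(np.mean(v)) for t, v in vafs.items()}
    return {"per_tier_exposures": table.to_dict(orient="records"),
            "mean_vaf_by_tier": mean_vaf}


def _stage_sv(bundle, pipe) -> dict:
    if bundle.svs is None or bundle.svs.empty:
        return {}
    svs = bundle.svs.copy()
    flags = []
    for sample, sub in svs.groupby("sample"):
        f = sv.detect_clustered_breakpoints(sub)
        flags.append(f)
    svs["clustered"] = pd.concat(flags).reindex(svs.index)
    spectrum = sv.build_rs_features(svs.drop_duplicates("name"), source="cohort")
    rs_catalog = make_rs_catalog(seed=pipe.seed)
    exposure = signatures.refit_exposures(spectrum, rs_catalog)
    # repair mechanisms per temporal tier
    repair = {}
    for case in _multi_tumor_cases(bundle):
        tumors = bundle.tumors_of_case(case)
        case_svs = svs[svs["sample"].isin(tumors)]
        tiers = sv.tier_svs(case_svs, tumors)
        fam = case_svs.drop_duplicates("name").set_index("name")
        for tier in ("early", "intermediate", "late"):
            names = tiers.index[tiers == tier]
            if len(names) == 0:
                continue
            fr = sv.repair_mechanism_fractions(fam.loc[names, "homlen"])
            repair.setdefault(tier, []).append(fr)
    repair_fractions = {
        tier: pd.concat(parts, axis=1).mean(axis=1).to_dict()
        for tier, parts in repair.items()
    }
    n_tumors = svs["sample"].nunique()
    gene_rows = svs[svs["gene"] != ""][["sample", "gene"]]
    recurrent = sv.sv_gene_recurrence(gene_rows, n_tumors,
                                      min_fraction=pipe.sv_recurrence_fraction)
    tra = sv.recurrent_translocations(svs, min_tumors=pipe.translocation_min_tumors)
    return {
        "rs_spectrum": spectrum.to_series().to_dict(),
        "rs_exposures": exposure.proportions.to_dict(),
        "repair_fractions_by_tier": repair_fractions,
        "recurrent_sv_genes": recurrent.to_dict(orient="records"),
        "recurrent_translocations": tra.to_dict(orient="records"),
    }


def _stage_cna(bundle, pipe) -> dict:
    cna = bundle.cna
    if cna is None or "cohort" not in cna.columns:
        return {}
    out = {}
    def table(cohort, event):
        return selection.build_patient_event_table(
            cna[cna.cohort == cohort], event)
    for event in ("amp", "del"):
        ram, naive = table("ram", event), table("naive", event)
        enr = selection.fisher_cna_enrichment(ram, naive, alpha=pipe.bh_alpha)
        out[f"ram_vs_naive_{event}"] = enr[enr.enriched]["gene"].tolist()
        mk_post, mk_pre = table("mapki_post", event), table("mapki_pre", event)
        enr2 = selection.fisher_cna_enrichment(mk_post, mk_pre, alpha=pipe.bh_alpha)
        out[f"mapki_post_vs_pre_{event}"] = enr2[enr2.enriched]["gene"].tolist()
        icb = selection.icb_enrichment(table("icb_post", event),
                                       table("icb_pre", event))
        out[f"icb_post_vs_pre_{event}"] = icb[icb.enriched]["gene"].tolist()
    return out


def _stage_clonality(bundle, pipe) -> dict:
    tumors = bundle.manifest[bundle.manifest.compartment == "tumor"]
    ram_cna = None
    if bundle.cna is not None and "cohort" in bundle.cna.columns:
        ram_cna = bundle.cna[bundle.cna.cohort == "ram"]
    ccf = clonality.estimate_ccf_table(bundle.mutations, bundle.manifest,
                                       cna=ram_cna,
                                       clonal_cutoff=pipe.clonal_cutoff)
    carried = ccf[ccf["t_alt_reads"] >= pipe.presence_min_alt_reads]
    ith = {
        sample: clonality.compute_ith(sub["ccf"], clonal_cutoff=pipe.clonal_cutoff)
        for sample, sub in carried.groupby("sample")
    }
    pref = clonality.organ_preferential_genes(
        carried, bundle.manifest, delta_cutoff=pipe.delta_ccf,
        min_patients=pipe.organ_min_patients)
    return {"ith_by_tumor": ith,
            "organ_preferential_genes": pref.to_dict(orient="records")}


def _tumor_pair_comparisons(bundle):
    """(case, organ_of_interest, tumor_A, tumor_B, nan_A, nan_B) tuples for
    all cross-organ tumor pairs with organ-matched distant normals."""
    m = bundle.manifest
    for case in sorted(m.case_id.unique()):
        sub = m[m.case_id == case]
        tum = sub[sub.compartment == "tumor"]
        nans = sub[sub.compartment == "NAN"].set_index("organ")["sample_id"]
        for ta, tb in itertools.permutations(tum.itertuples(index=False), 2):
            if ta.organ == tb.organ:
                continue
            if ta.organ not in nans.index or tb.organ not in nans.index:
                continue
            yield (case, ta.organ, ta.sample_id, tb.sample_id,
                   nans[ta.organ], nans[tb.organ])


def _stage_transcriptome(bundle, pipe, gene_sets) -> dict:
    counts = bundle.expression
    m = bundle.manifest.set_index("sample_id")
    rna = [s for s in counts.columns if s in m.index]
    log2cpm = tx.normalize_log2cpm(counts[rna])
    cpm = tx.cpm(counts[rna])
    nan_samples = [s for s in rna if m.loc[s, "compartment"] == "NAN"]
    organ_of = m.loc[nan_samples, "organ"]
    signatures_by_organ = tx.organ_normal_signatures(log2cpm[nan_samples], organ_of)
    # organ-normal signature scores in tumors (purity anticorrelation readout)
    tumor_samples = [s for s in rna if m.loc[s, "compartment"] == "tumor"]
    organ_scores = {}
    for s in tumor_samples:
        sig = signatures_by_organ.get(m.loc[s, "organ"], [])
        if sig:
            organ_scores[s] = tx.ss_enrichment_score(log2cpm[s], sig)
    calls = []
    for case, organ, ta, tb, na, nb in _tumor_pair_comparisons(bundle):
        rec = tx.nc_fc(cpm[ta], cpm[tb], cpm[na], cpm[nb],
                       up_cutoff=pipe.nc_fc_up, down_cutoff=pipe.nc_fc_down)
        hit = rec[rec.direction != "none"]
        for gene, r in hit.iterrows():
            calls.append({"comparison_id": f"{ta}|{tb}", "case": case,
                          "organ": organ, "gene": gene,
                          "direction": r["direction"]})
    calls_df = pd.DataFrame(calls, columns=["comparison_id", "case", "organ",
                                            "gene", "direction"])
    recurrent = tx.nc_deg_recurrence(calls_df, min_fraction=pipe.nc_recurrence,
                                     min_cases=pipe.nc_min_cases)
    return {
        "organ_normal_signatures": signatures_by_organ,
        "organ_signature_scores_in_tumors": organ_scores,
        "recurrent_nc_degs": recurrent.to_dict(orient="records"),
    }


def _stage_immune(bundle, pipe, gene_sets) -> dict:
    counts = bundle.expression
    m = bundle.manifest.set_index("sample_id")
    rna = [s for s in counts.columns if s in m.index]
    log2cpm = tx.normalize_log2cpm(counts[rna])
    archetype_sets = {k: v for k, v in gene_sets.items()
                      if k.startswith("archetype_")}
    assignments = immune.assign_archetypes(log2cpm, archetype_sets)
    comp = immune.archetype_composition(assignments, bundle.manifest)
    programs = {k: gene_sets[k] for k in ("t_cell_exhaustion", "type2_immunity")
                if k in gene_sets}
    scores = immune.score_programs(log2cpm, programs, bundle.manifest)
    return {
        "archetype_labels": assignments["label"].to_dict(),
        "composition": comp.to_dict(orient="records"),
        "program_scores": {k: scores[k].round(6).to_dict() for k in programs},
    }
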