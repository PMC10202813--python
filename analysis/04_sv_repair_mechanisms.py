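"""Rearrangement classes, RS32 exposures and DSB-repair inference.

Classifies SVs as clustered/non-clustered, builds the 32-channel
rearrangement spectrum and refits it against the RS catalog, then infers
the double-strand-break repair mechanism of each junction from its
homology length (0-1 bp NHEJ, 2-6 bp alternative NHEJ, >6 bp HRR),
stratified by temporal tier. Also reports recurrently SV-hit genes
(>=50% of tumors) and recurrent translocation windows.
"""

import pandas as pd

from _common import RESULTS, get_cohort
from ramscape import signatures, sv
from ramscape.simulate import make_rs_catalog


def main():
    bundle, truth = get_cohort()
    svs = bundle.svs.copy()
    flags = [sv.detect_clustered_breakpoints(g) for _, g in svs.groupby("sample")]
    svs["clustered"] = pd.concat(flags).reindex(svs.index)
    fam = svs.drop_duplicates("name")
    spectrum = sv.build_rs_features(fam, source="cohort")
    exposure = signatures.refit_exposures(spectrum, make_rs_catalog(seed=11))
    print("RS exposures:", exposure.proportions.round(3).to_dict())

    rows = []
    for case in sorted(bundle.manifest.case_id.unique()):
        tumors = bundle.tumors_of_case(case)
        case_svs = svs[svs["sample"].isin(tumors)]
        tiers = sv.tier_svs(case_svs, tumors)
        fam_case = case_svs.drop_duplicates("name").set_index("name")
        for tier in ("early", "intermediate", "late"):
            names = tiers.index[tiers == tier]
            if len(names) == 0:
                continue
            fr = sv.repair_mechanism_fractions(fam_case.loc[names, "homlen"])
            rows.append({"case": case, "tier": tier, **fr.to_dict(),
                         "n_svs": len(names)})
    repair = pd.DataFrame(rows)
    repair.to_csv(RESULTS / "sv_repair_by_tier.tsv", sep="\t", index=False)
    early = repair[repair.tier == "early"]
    nhej = (early["NHEJ"] * early["n_svs"]).sum() / early["n_svs"].sum()
    print(f"NHEJ fraction among early SVs: {100 * nhej:.1f}%")

    n_tumors = svs["sample"].nunique()
    genes = sv.sv_gene_recurrence(svs[svs.gene != ""][["sample", "gene"]],
                                  n_tumors, 0.5)
    genes.to_csv(RESULTS / "sv_recurrent_genes.tsv", sep="\t", index=False)
    tra = sv.recurrent_translocations(svs, min_tumors=4)
    tra.to_csv(RESULTS / "sv_recurrent_translocations.tsv", sep="\t", index=False)
    print(f"{len(genes)} genes hit by SVs in >= {genes['threshold'].iloc[0] if len(genes) else '-'}"
          f"/{n_tumors} tumors; {len(tra)} recurrent translocation windows")
    print(f"tables -> {RESULTS}/sv_*.tsv")


if __name__ == "__main__":
    main()
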