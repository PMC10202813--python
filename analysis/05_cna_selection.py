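"""Patient-level copy-number enrichment across cohorts.

Three rules: (1) autopsy cohort vs the large therapy-naive comparator,
two-sided Fisher per gene with BH correction and a higher-frequency
requirement; (2) the same Fisher rule for post- vs pre-treatment tumors of
the MAPK-inhibitor arm; (3) the fold rule for the checkpoint-blockade arm
(post frequency > 2x pre, >= 2 post patients). Implanted genes should be
recovered; background genes should stay quiet.
"""

import pandas as pd

from _common import RESULTS, get_cohort
from ramscape import selection


def main():
    bundle, truth = get_cohort()
    cna = bundle.cna

    def table(cohort, event):
        return selection.build_patient_event_table(cna[cna.cohort == cohort], event)

    frames = []
    for event in ("amp", "del"):
        f = selection.fisher_cna_enrichment(table("ram", event),
                                            table("naive", event))
        f.insert(0, "rule", f"ram_vs_naive_{event}")
        frames.append(f)
        f2 = selection.fisher_cna_enrichment(table("mapki_post", event),
                                             table("mapki_pre", event))
        f2.insert(0, "rule", f"mapki_post_vs_pre_{event}")
        frames.append(f2)
        icb = selection.icb_enrichment(table("icb_post", event),
                                       table("icb_pre", event))
        icb.insert(0, "rule", f"icb_post_vs_pre_{event}")
        frames.append(icb.rename(columns={"freq_post": "freq_a",
                                          "freq_pre": "freq_b"}))
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(RESULTS / "cna_enrichment.tsv", sep="\t", index=False)
    hits = out[out.enriched]
    for rule, g in hits.groupby("rule"):
        print(f"{rule:24s} {sorted(g.gene)}")
    implanted = truth["cna_implants"]["ram_vs_naive"]
    found = set(hits[hits.rule.str.startswith("ram_")]["gene"])
    print(f"implanted autopsy-enriched genes recovered: "
          f"{len(found & set(implanted))}/{len(implanted)}")
    print(f"table -> {RESULTS / 'cna_enrichment.tsv'}")


if __name__ == "__main__":
    main()
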