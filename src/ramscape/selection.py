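"""Patient-level copy-number event counting and cohort enrichment rules.

Copy-number events are counted at the patient level: a gene is amplified or
deleted in a patient when the call appears in at least one of that patient's
tumors (multiple tumors per patient are an entirety). Three enrichment rules
are implemented:

* Fisher rule — two-sided Fisher's exact test per gene on patient-level
  frequencies between two cohorts, Benjamini-Hochberg adjusted; enriched
  requires adjusted P < alpha AND a higher frequency in cohort A. Used for
  autopsy-vs-comparator and for post-vs-pre MAPK-inhibitor comparisons.
* ICB fold rule — post frequency strictly greater than 2x the pre frequency
  and the event present in >= 2 patients' post tumors.
* Gene-set overlap — upper-tail hypergeometric test.

Also houses expression-binned nomination of significantly mutated genes
(SMGs) and bi-allelic loss detection (deletion of one copy plus deleterious
mutation of the other).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DELETERIOUS_CLASSES = ("nonsense", "frameshift", "splice_site", "lof_missense")

# Stage strata of the BRAF/NRAS-mutant TCGA skin-melanoma comparator cohort
# used for the copy-number frequency comparisons.
SKCM_COMPARATOR_STRATA = {
    "stage_0": 7, "stage_1": 65, "stage_2": 100, "stage_3": 130,
    "stage_4": 17, "unknown": 26,
}


def comparator_cohort_size(strata: dict | None = None) -> int:
    """Total comparator patients across stage strata."""
    strata = SKCM_COMPARATOR_STRATA if strata is None else strata
    if any(v < 0 for v in strata.values()):
        raise ValueError("stratum sizes must be non-negative")
    return int(sum(strata.values()))


def build_patient_event_table(cna: pd.DataFrame, event_type: str,
                              case_column: str = "case") -> pd.DataFrame:
    """Gene x patient boolean table: OR over each patient's tumors."""
    if event_type not in ("amp", "del"):
        raise ValueError(f"unknown event_type {event_type!r}")
    hits = cna[cna["call"] == event_type]
    patients = sorted(cna[case_column].unique())
    genes = sorted(cna["gene"].unique())
    table = (
        hits.assign(one=True)
        .pivot_table(index="gene", columns=case_column, values="one",
                     aggfunc="any", fill_value=False)
        .reindex(index=genes, columns=patients, fill_value=False)
    )
    return table.astype(bool)


def fisher_cna_enrichment(table_a: pd.DataFrame, table_b: pd.DataFrame,
                          alpha: float = 0.05,
                          genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene two-sided Fisher's exact test between patient-event tables.

    The gene universe defaults to the intersection of genes assayed in both
    cohorts. Enriched: BH-adjusted P < alpha AND freq_a > freq_b.
    """
    n_a, n_b = table_a.shape[1], table_b.shape[1]
    if n_a == 0 or n_b == 0:
        raise ValueError("both cohorts need at least one patient")
    if genes is None:
        genes = sorted(set(table_a.index) & set(table_b.index))
    rows = []
    for gene in genes:
        k_a = int(table_a.loc[gene].sum()) if gene in table_a.index else 0
        k_b = int(table_b.loc[gene].sum()) if gene in table_b.index else 0
        _, p = stats.fisher_exact([[k_a, n_a - k_a], [k_b, n_b - k_b]],
                                  alternative="two-sided")
        rows.append({"gene": gene, "k_a": k_a, "k_b": k_b,
                     "freq_a": k_a / n_a, "freq_b": k_b / n_b, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out["p_adj"] = out["enriched"] = []
        return out
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enriched"] = (out["p_adj"] < alpha) & (out["freq_a"] > out["freq_b"])
    return out.sort_values("p").reset_index(drop=True)


def icb_fold_rule(freq_post: float, freq_pre: float, n_post_patients: int) -> bool:
    """Post-treatment enrichment under the checkpoint-blockade rule:
    post frequency strictly > 2x pre frequency, in >= 2 patients' post
    tumors. A pre frequency of 0 with any positive post frequency satisfies
    the fold condition."""
    return bool(freq_post > 2.0 * freq_pre and n_post_patients >= 2)


def icb_enrichment(table_post: pd.DataFrame, table_pre: pd.DataFrame) -> pd.DataFrame:
    """Apply the fold rule across a gene universe (intersection of tables)."""
    genes = sorted(set(table_post.index) & set(table_pre.index))
    n_post, n_pre = table_post.shape[1], table_pre.shape[1]
    rows = []
    for gene in genes:
        k_post = int(table_post.loc[gene].sum())
        k_pre = int(table_pre.loc[gene].sum())
        rows.append({
            "gene": gene, "freq_post": k_post / n_post, "freq_pre": k_pre / n_pre,
            "n_post_patients": k_post,
            "enriched": icb_fold_rule(k_post / n_post, k_pre / n_pre, k_post),
        })
    return pd.DataFrame(rows)


def geneset_overlap_test(set_a, set_b, universe) -> float:
    """Upper-tail hypergeometric P of observing >= the actual overlap."""
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    # P(X >= k) where X ~ Hypergeom(N, K, n)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def nominate_smgs(gene_p: pd.DataFrame, mean_log2cpm: pd.Series,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Expression-binned nomination of significantly mutated genes.

    ``gene_p`` has columns (gene, p) — per-gene mutation-significance
    P values supplied as input (raw, no multiple-testing adjustment by
    design). Genes at p < alpha are binned by mean tumor expression:
    mean log2CPM < 0 -> no expression (excluded from the nominated list),
    [0, 4) -> expressed, >= 4 -> highly expressed. Genes without an
    expression summary land in an explicit 'unscored' bin.
    """
    if ((gene_p["p"] < 0) | (gene_p["p"] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    sig = gene_p[gene_p["p"] < alpha].copy()
    expr = sig["gene"].map(mean_log2cpm)
    bins = pd.Series("unscored", index=sig.index, dtype=object)
    bins[expr < 0] = "no_expression"
    bins[(expr >= 0) & (expr < 4)] = "expressed"
    bins[expr >= 4] = "highly_expressed"
    sig["mean_log2cpm"] = expr
    sig["bin"] = bins
    sig["nominated"] = bins.isin(["expressed", "highly_expressed"])
    return sig.reset_index(drop=True)


def detect_biallelic_loss(gene: str, mutations: pd.DataFrame,
                          cna: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor bi-allelic loss: copy-number deletion plus a deleterious
    mutation of the retained copy in the same tumor.

    Tumors with two or more deleterious mutations but no deletion are
    reported as 'possible_compound' (phasing unavailable), not bi-allelic.
    """
    muts = mutations[(mutations["gene"] == gene)
                     & (mutations["class"].isin(DELETERIOUS_CLASSES))]
    dels = set(cna[(cna["gene"] == gene) & (cna["call"] == "del")]["sample"])
    rows = []
    for sample, sub in muts.groupby("sample"):
        n_del_mut = len(sub)
        has_del = sample in dels
        rows.append({
            "sample": sample, "gene": gene, "n_deleterious": n_del_mut,
            "has_deletion": has_del,
            "biallelic": has_del and n_del_mut >= 1,
            "possible_compound": (not has_del) and n_del_mut >= 2,
        })
    for sample in sorted(dels - set(muts["sample"])):
        rows.append({"sample": sample, "gene": gene, "n_deleterious": 0,
                     "has_deletion": True, "biallelic": False,
                     "possible_compound": False})
    return pd.DataFrame(rows)
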