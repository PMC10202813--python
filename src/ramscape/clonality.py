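"""Closed-form cancer cell fraction (CCF) estimation and downstream calls.

For a mutation with variant allele frequency ``v`` in a tumor of purity
``rho`` with local tumor copy number ``CNt`` (normal copy number ``CNn``,
default 2), the fraction of sequenced alleles carrying the variant is

    v = rho * CCF * m / (rho * CNt + (1 - rho) * CNn)

where ``m`` is the number of tumor copies bearing the variant. The point
estimator inverts this: ``m`` is the rounded value of
``v * (rho*CNt + (1-rho)*CNn) / rho`` clamped into ``{1..CNt}``, and CCF is
the corresponding plug-in, clipped to [0, 1.5] for reporting. Mutations with
CCF at or above a cutoff (default 0.8) are called clonal; the subclonal
fraction is the intratumoral-heterogeneity (ITH) index. Organ-preferential
genes come from per-case CCF differences between one organ's tumor and the
mean over tumors of other organs (ΔCCF > 0.2, recurring in >= 3 patients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CcfEstimate:
    ccf: float
    multiplicity: int
    clonal: bool


def estimate_ccf(vaf: float, purity: float, tumor_cn: int = 2,
                 normal_cn: int = 2, clonal_cutoff: float = 0.8) -> CcfEstimate:
    """Closed-form CCF point estimate for one mutation."""
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    if tumor_cn < 1:
        raise ValueError("tumor copy number must be >= 1")
    if not (0 <= vaf <= 1):
        raise ValueError("VAF must be in [0, 1]")
    denom = purity * tumor_cn + (1 - purity) * normal_cn
    alleles = vaf * denom / purity          # expected mutant alleles per cancer cell
    m = int(np.clip(np.round(alleles), 1, tumor_cn))
    ccf = float(np.clip(alleles / m, 0.0, 1.5))
    return CcfEstimate(ccf=ccf, multiplicity=m, clonal=ccf >= clonal_cutoff)


def estimate_ccf_table(mutations: pd.DataFrame, manifest: pd.DataFrame,
                       cna: pd.DataFrame | None = None,
                       clonal_cutoff: float = 0.8) -> pd.DataFrame:
    """Vectorised CCF estimates for a mutation table.

    Purity joins from the manifest by sample; local tumor copy number joins
    from gene-level CNA calls when provided (``total_cn``), else 2.
    """
    purity = manifest.set_index("sample_id")["purity"]
    df = mutations.copy()
    df["purity"] = df["sample"].map(purity)
    if df["purity"].isna().any():
        bad = df.loc[df["purity"].isna(), "sample"].unique()[:3]
        raise ValueError(f"missing purity for samples {list(bad)}")
    df["vaf"] = df["t_alt_reads"] / df["t_depth"].clip(lower=1)
    cnt = np.full(len(df), 2.0)
    if cna is not None:
        cn_map = cna.set_index(["sample", "gene"])["total_cn"]
        keys = pd.MultiIndex.from_arrays([df["sample"], df["gene"]])
        joined = cn_map.reindex(keys).to_numpy(float)
        cnt = np.where(np.isnan(joined), 2.0, np.maximum(joined, 1.0))
    denom = df["purity"] * cnt + (1 - df["purity"]) * 2.0
    alleles = df["vaf"] * denom / df["purity"]
    m = np.clip(np.round(alleles), 1, cnt).astype(int)
    df["multiplicity"] = m
    df["ccf"] = np.clip(alleles / m, 0.0, 1.5)
    df["clonal"] = df["ccf"] >= clonal_cutoff
    return df


def compute_ith(ccfs, clonal_cutoff: float = 0.8) -> float:
    """Subclonal fraction: |{CCF < cutoff}| / total."""
    arr = np.asarray(list(ccfs), dtype=float)
    if arr.size == 0:
        raise ValueError("ITH undefined for an empty mutation set")
    return float((arr < clonal_cutoff).mean())


def organ_preferential_genes(ccf_table: pd.DataFrame, manifest: pd.DataFrame,
                             delta_cutoff: float = 0.2, min_patients: int = 3,
                             reference: str = "mean",
                             nonsynonymous_classes=("missense", "nonsense",
                                                    "frameshift", "splice_site",
                                                    "inframe")) -> pd.DataFrame:
    """Genes whose mutations prefer one organ's tumors across patients.

    Per case and mutation: ΔCCF = CCF in the organ-A tumor minus the
    mean (or max, ``reference='max'``) CCF of the same mutation across
    tumors of other organs (absent mutations count as CCF 0). A mutation is
    organ-enriched when ΔCCF > ``delta_cutoff`` (strict); a gene is reported
    for organ A when enriched mutations in it occur in >= ``min_patients``
    distinct cases. Only non-synonymous classes are considered. Cases whose
    tumors all come from one organ are skipped.
    """
    if reference not in ("mean", "max"):
        raise ValueError("reference must be 'mean' or 'max'")
    organ = manifest.set_index("sample_id")["organ"]
    df = ccf_table[ccf_table["class"].isin(nonsynonymous_classes)].copy()
    df["organ"] = df["sample"].map(organ)
    hits = []  # (organ, gene, case)
    for case, sub in df.groupby("case"):
        tumors = manifest[(manifest["case_id"] == case)
                          & (manifest["compartment"] == "tumor")]
        organs_present = tumors["organ"].unique()
        if len(organs_present) < 2:
            continue
        tumor_organ = tumors.set_index("sample_id")["organ"]
        # CCF per mutation per tumor, absent -> 0
        pivot = sub.pivot_table(index="mutation_id", columns="sample",
                                values="ccf", aggfunc="max")
        pivot = pivot.reindex(columns=tumor_organ.index, fill_value=0.0).fillna(0.0)
        gene_of = sub.drop_duplicates("mutation_id").set_index("mutation_id")["gene"]
        for org in organs_present:
            own = [s for s in pivot.columns if tumor_organ[s] == org]
            other = [s for s in pivot.columns if tumor_organ[s] != org]
            if not own or not other:
                continue
            own_ccf = pivot[own].max(axis=1)
            ref_ccf = (pivot[other].mean(axis=1) if reference == "mean"
                       else pivot[other].max(axis=1))
            delta = own_ccf - ref_ccf
            enriched = delta[delta > delta_cutoff].index
            for mut in enriched:
                hits.append((org, gene_of[mut], case))
    if not hits:
        return pd.DataFrame(columns=["organ", "gene", "n_patients"])
    hit_df = pd.DataFrame(hits, columns=["organ", "gene", "case"]).drop_duplicates()
    counts = hit_df.groupby(["organ", "gene"])["case"].nunique().rename("n_patients")
    out = counts[counts >= min_patients].reset_index()
    return out.sort_values(["organ", "n_patients"], ascending=[True, False]).reset_index(drop=True)


def allelic_ratio(vaf: float) -> float:
    """Variant-to-normal allele ratio, vaf / (1 - vaf)."""
    if not (0 <= vaf < 1):
        raise ValueError("VAF must be in [0, 1) for an allelic ratio")
    return vaf / (1.0 - vaf)
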