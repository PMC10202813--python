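"""Expression normalisation and normal-contamination-corrected differential
analysis.

Bulk tumor transcriptomes from autopsy metastases are mixtures of tumor cells
and the host organ's normal tissue; naive between-organ comparisons of tumors
therefore rediscover organ physiology. The normal-corrected fold change
(NC-FC) divides the tumor-pair fold change of a gene by the fold change of
the same gene between the matched normal tissues of the same two organs:

    NC-FC(g; A, B) = FC_tumor(g; T_A, T_B) / FC_normal(g; N_A, N_B)

Genes with NC-FC > 2 (up) or < 0.5 (down) are normal-corrected DEGs; a gene
is recurrent for organ A when called in the same direction in >= 30% of all
organ-A-vs-other-organ comparisons and in >= 3 distinct cases. Differential
gene sets get the analogous treatment at the enrichment level (NC-DGS):
tumor-side significant sets whose (set, sign) pair is absent from the
matched normal compartment.

Also provides log2-CPM normalisation, rank-sum-based organ-normal marker
signatures, a rank-based single-sample enrichment score, preranked GSEA with
a permutation null, and an over-representation (hypergeometric) test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ramscape.rng import substream


# --- normalisation -----------------------------------------------------------

def cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Counts per million with pseudocount: (c + pc) / (libsize + 1) * 1e6."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"zero library size for sample {bad}")
    return (counts + pseudocount).div(lib + 1.0, axis=1) * 1e6


def normalize_log2cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 of CPM with pseudocount; finite for zero counts."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log2(cpm(counts, pseudocount))


# --- organ-normal signatures -------------------------------------------------

def organ_normal_signatures(log2cpm: pd.DataFrame, organ_of_sample: pd.Series,
                            top_n: int = 5, fdr: float = 0.05) -> dict[str, list[str]]:
    """Top upregulated marker genes per organ from distant-normal samples.

    For each organ: rank-sum (Mann-Whitney) test per gene of that organ's
    samples against all others on log2CPM, BH-adjusted; among genes with
    FDR < ``fdr`` and positive effect, the ``top_n`` by mean log2CPM
    difference. Fewer than ``top_n`` significant genes returns fewer.
    """
    counts = organ_of_sample.value_counts()
    organs = sorted(counts.index[counts >= 2])
    if len(organs) < 2:
        raise ValueError("need >= 2 organs with >= 2 samples each")
    out = {}
    X = log2cpm[organ_of_sample.index]
    for organ in organs:
        own = organ_of_sample.index[organ_of_sample == organ]
        rest = organ_of_sample.index[organ_of_sample != organ]
        if len(rest) < 2:
            continue
        a, b = X[own].to_numpy(), X[rest].to_numpy()
        effect = a.mean(axis=1) - b.mean(axis=1)
        with np.errstate(invalid="ignore"):
            _, p = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        p = np.nan_to_num(p, nan=1.0)
        padj = multipletests(p, method="fdr_bh")[1]
        sig = pd.Series(effect, index=X.index)[(padj < fdr) & (effect > 0)]
        out[organ] = list(sig.sort_values(ascending=False).head(top_n).index)
    return out


# --- single-sample enrichment ------------------------------------------------

def ss_enrichment_score(sample: pd.Series, gene_set, weight: float = 0.25) -> float:
    """Rank-based single-sample enrichment score of a gene set.

    Genes are ordered by decreasing expression; the score is the maximal
    deviation of a weighted running sum in which set genes step up in
    proportion to their rank score raised to ``weight`` and non-set genes
    step down uniformly. Deterministic per sample (ties break on gene name);
    invariant under strictly monotone transforms of the expression vector.
    """
    genes_in = [g for g in gene_set if g in sample.index]
    if not genes_in:
        raise ValueError("gene set has no overlap with the expression index")
    order = sample.sort_values(ascending=False, kind="mergesort")
    order = order.loc[sorted(order.index, key=lambda g: (-order[g], g))]
    n = len(order)
    in_set = order.index.isin(set(genes_in))
    rank_score = np.arange(n, 0, -1, dtype=float) ** weight
    hit = np.where(in_set, rank_score, 0.0)
    hit = np.cumsum(hit) / hit.sum()
    n_miss = n - in_set.sum()
    miss = np.cumsum(np.where(in_set, 0.0, 1.0)) / max(n_miss, 1)
    dev = hit - miss
    return float(dev[np.argmax(np.abs(dev))])


# --- NC-FC and recurrence ----------------------------------------------------

def nc_fc(tumor_a: pd.Series, tumor_b: pd.Series, normal_a: pd.Series,
          normal_b: pd.Series, up_cutoff: float = 2.0,
          down_cutoff: float = 0.5) -> pd.DataFrame:
    """Normal-corrected fold changes for one tumor pair.

    Inputs are per-sample CPM vectors (or replicate means) over a shared
    gene universe. Returns per gene: FC_T, FC_N, NC-FC and direction in
    {up, down, none}.
    """
    idx = tumor_a.index
    for other in (tumor_b, normal_a, normal_b):
        if not idx.equals(other.index):
            raise ValueError("all four samples must share the gene universe")
    fc_t = tumor_a / tumor_b
    fc_n = normal_a / normal_b
    nc = fc_t / fc_n
    direction = pd.Series("none", index=idx, dtype=object)
    direction[nc > up_cutoff] = "up"
    direction[nc < down_cutoff] = "down"
    return pd.DataFrame({"fc_t": fc_t, "fc_n": fc_n, "nc_fc": nc,
                         "direction": direction})


def nc_deg_recurrence(calls: pd.DataFrame, min_fraction: float = 0.30,
                      min_cases: int = 3) -> pd.DataFrame:
    """Recurrent normal-corrected DEGs per organ and direction.

    ``calls`` holds one row per (comparison_id, case, organ, gene, direction)
    NC-DEG call, where ``organ`` is the organ of interest of the comparison.
    A gene is recurrent for (organ, direction) when it is called in
    >= ``min_fraction`` of all comparisons run for that organ AND in
    >= ``min_cases`` distinct cases. Opposite directions never merge.
    """
    required = {"comparison_id", "case", "organ", "gene", "direction"}
    if not required <= set(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    n_comparisons = calls.groupby("organ")["comparison_id"].nunique()
    rows = []
    for (organ, direction, gene), sub in calls[calls["direction"] != "none"].groupby(
            ["organ", "direction", "gene"]):
        frac = sub["comparison_id"].nunique() / n_comparisons[organ]
        n_case = sub["case"].nunique()
        if frac >= min_fraction and n_case >= min_cases:
            rows.append({"organ": organ, "direction": direction, "gene": gene,
                         "recurrence": frac, "n_cases": n_case})
    return pd.DataFrame(rows, columns=["organ", "direction", "gene",
                                       "recurrence", "n_cases"])


# --- preranked GSEA ----------------------------------------------------------

def _weighted_ks_es(metric: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov enrichment statistic on a sorted ranking."""
    w = np.abs(metric) * in_set
    total = w.sum()
    if total == 0:
        w = in_set.astype(float)
        total = w.sum()
    hit = np.cumsum(w) / total
    n_miss = len(metric) - in_set.sum()
    miss = np.cumsum(~in_set) / max(n_miss, 1)
    dev = hit - miss
    return float(dev[np.argmax(np.abs(dev))])


def preranked_gsea(ranking: pd.Series, gene_set, n_perm: int = 1000,
                   seed: int = 0, stream: str = "gsea") -> dict:
    """Preranked GSEA with a gene-label permutation null.

    ``ranking`` maps gene -> metric (e.g., log2 fold change), any order.
    ES is the weighted KS statistic over the metric-sorted ranking; the null
    permutes set membership over genes ``n_perm`` times. The p-value
    conditions on the sign of the observed ES; NES divides ES by the mean
    |null ES| of the same sign.
    """
    genes = set(gene_set)
    if not genes <= set(ranking.index):
        raise ValueError("gene set must be contained in the ranking universe")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    order = ranking.sort_values(ascending=False, kind="mergesort")
    metric = order.to_numpy(float)
    in_set = order.index.isin(genes)
    es = _weighted_ks_es(metric, in_set)
    rng = substream(seed, stream)
    k = int(in_set.sum())
    n = len(order)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        null[i] = _weighted_ks_es(metric, perm)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        p, nes = 1.0 / (n_perm + 1), np.sign(es) * float("inf")
    else:
        p = (1 + (np.abs(same_sign) >= abs(es)).sum()) / (1 + same_sign.size)
        nes = es / np.abs(same_sign).mean()
    return {"es": es, "nes": float(nes), "p": float(p), "n_genes": k}


def gsea_collection(ranking: pd.Series, gene_sets: dict, n_perm: int = 1000,
                    seed: int = 0) -> pd.DataFrame:
    """Preranked GSEA over a set collection with BH FDR across sets."""
    rows = []
    for name, genes in gene_sets.items():
        usable = [g for g in genes if g in ranking.index]
        if not usable:
            continue
        res = preranked_gsea(ranking, usable, n_perm=n_perm, seed=seed,
                             stream=f"gsea:{name}")
        rows.append({"set": name, **res})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def nc_dgs(tumor_dgs: pd.DataFrame, nan_dgs: pd.DataFrame) -> pd.DataFrame:
    """Normal-corrected differential gene sets.

    Keep tumor-side significant sets whose (set, sign of NES) pair does not
    appear among the matched normal compartment's significant sets. A set
    significant in both but with opposite signs is kept (sign-aware).
    """
    def keyed(df):
        return {(r.set, np.sign(r.nes)) for r in df.itertuples(index=False)}

    nan_keys = keyed(nan_dgs) if not nan_dgs.empty else set()
    keep = [
        (r.set, np.sign(r.nes)) not in nan_keys
        for r in tumor_dgs.itertuples(index=False)
    ]
    return tumor_dgs.loc[keep].reset_index(drop=True)


# --- over-representation -----------------------------------------------------

def ora_test(gene_list, annotation_sets: dict, universe, top_k: int = 5) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in annotation sets."""
    universe = set(universe)
    gene_list = set(gene_list)
    if not gene_list:
        raise ValueError("empty gene list")
    if not gene_list <= universe:
        raise ValueError("gene list must be a subset of the universe")
    N, n = len(universe), len(gene_list)
    rows = []
    for name, genes in annotation_sets.items():
        K = len(set(genes) & universe)
        k = len(set(genes) & gene_list)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "overlap": k, "set_size": K, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out.sort_values(["p_adj", "p", "set"]).reset_index(drop=True)
    out["top"] = False
    out.loc[: top_k - 1, "top"] = True
    return out
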