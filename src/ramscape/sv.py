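"""Structural-variant classification, repair-mechanism inference, and
recurrence analyses.

Double-strand-break repair is inferred from the homologous-sequence length at
the rearrangement junction: 0-1 bp implies non-homologous end joining (NHEJ),
2-6 bp microhomology-mediated (alternative) NHEJ, and >6 bp homologous
recombination repair (HRR). Rearrangement-signature (RS32) features follow
the breast-cancer rearrangement classification: clustered vs non-clustered
deletions, duplications and inversions in five size bins plus translocations.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
import pandas as pd

from ramscape import channels as ch
from ramscape.signatures import Spectrum

NHEJ, ALT_NHEJ, HRR = "NHEJ", "alt-NHEJ", "HRR"


def classify_junction(homlen: int, nhej_max: int = 1, alt_max: int = 6) -> str:
    """Repair mechanism from junction homology length (bp)."""
    if homlen < 0:
        raise ValueError("homology length must be >= 0")
    if homlen <= nhej_max:
        return NHEJ
    if homlen <= alt_max:
        return ALT_NHEJ
    return HRR


def repair_mechanism_fractions(homlens) -> pd.Series:
    """Fraction of junctions attributed to each repair mechanism."""
    mechs = pd.Series([classify_junction(int(h)) for h in homlens])
    return mechs.value_counts(normalize=True).reindex(
        [NHEJ, ALT_NHEJ, HRR], fill_value=0.0)


def detect_clustered_breakpoints(svs: pd.DataFrame, window: float = 1e6,
                                 fold: float = 10.0,
                                 genome_size: float = 3.2e9) -> pd.Series:
    """Flag SVs with a breakpoint in a locally dense region.

    A breakpoint is clustered when the density of *other* breakpoints within
    a ``window`` centred on it is at least ``fold`` times the genome-wide
    average density (total breakpoints / ``genome_size``). An SV is clustered
    if either of its breakpoints is. Operates per genome (one tumor's SVs).
    """
    if svs.empty:
        return pd.Series(dtype=bool)
    ids = np.arange(len(svs))
    bp = pd.concat([
        svs[["chrom1", "start1"]].rename(columns={"chrom1": "chrom", "start1": "pos"})
        .assign(sv=ids),
        svs[["chrom2", "start2"]].rename(columns={"chrom2": "chrom", "start2": "pos"})
        .assign(sv=ids),
    ], ignore_index=True)
    n_total = len(bp)
    avg_density = n_total / genome_size
    threshold = fold * avg_density * window  # min count of other SVs' breakpoints
    by_chrom = {}
    for c, g in bp.groupby("chrom"):
        order = np.argsort(g["pos"].to_numpy(float), kind="stable")
        by_chrom[c] = (g["pos"].to_numpy(float)[order], g["sv"].to_numpy()[order])
    half = window / 2.0

    def bp_clustered(chrom, pos, sv_id) -> bool:
        arr, owners = by_chrom[chrom]
        lo = np.searchsorted(arr, pos - half, side="left")
        hi = np.searchsorted(arr, pos + half, side="right")
        n_others = hi - lo - int((owners[lo:hi] == sv_id).sum())
        return n_others >= threshold

    flags = [
        bp_clustered(r.chrom1, r.start1, i) or bp_clustered(r.chrom2, r.start2, i)
        for i, r in zip(ids, svs.itertuples(index=False))
    ]
    return pd.Series(flags, index=svs.index)


def build_rs_features(svs: pd.DataFrame, source: str = "") -> Spectrum:
    """RS32 rearrangement spectrum from SVs carrying a ``clustered`` flag.

    Every SV maps to exactly one channel; sizes come from ``start2 - start1``
    for intra-chromosomal types. Translocations are size-free.
    """
    if "clustered" not in svs.columns:
        raise ValueError("assign clustered flags before building RS features")
    counts = np.zeros(32)
    for r in svs.itertuples(index=False):
        svtype = str(r.svtype)
        size = None
        if svtype not in ("translocation", "tra"):
            size = abs(float(r.start2) - float(r.start1))
        label = ch.rs32_channel(svtype, bool(r.clustered), size)
        counts[ch.RS32_INDEX[label]] += 1
    return Spectrum("RS32", counts, source=source)


def sv_gene_recurrence(sv_genes: pd.DataFrame, n_tumors: int,
                       min_fraction: float = 0.5) -> pd.DataFrame:
    """Genes overlapped by SVs in at least ``min_fraction`` of tumors.

    ``sv_genes`` holds one row per (sample, gene) SV overlap. The count
    threshold is ``ceil(min_fraction * n_tumors)`` — e.g., 50% of 21 tumors
    requires 11.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    threshold = math.ceil(min_fraction * n_tumors)
    counts = (
        sv_genes.drop_duplicates(subset=["sample", "gene"])
        .groupby("gene").size().rename("n_tumors_affected")
    )
    out = counts[counts >= threshold].sort_values(ascending=False).reset_index()
    out["threshold"] = threshold
    return out


def recurrent_translocations(svs: pd.DataFrame, min_tumors: int = 4,
                             bin_size: float = 1e6,
                             arm_column: str | None = None) -> pd.DataFrame:
    """Translocation partner-window pairs recurring across tumors.

    Breakpoints are binned to ``bin_size`` windows; a pair is the unordered
    set of the two (chrom, window) partners. With ``arm_column`` set, counts
    are computed within each treatment-arm stratum instead (the per-arm
    sub-analysis uses a lower threshold).
    """
    tra = svs[svs["svtype"].isin(["translocation", "tra"])].copy()
    if tra.empty:
        return pd.DataFrame(columns=["pair", "n_tumors"])
    tra["w1"] = tra["chrom1"].astype(str) + ":" + (tra["start1"] // bin_size).astype(int).astype(str)
    tra["w2"] = tra["chrom2"].astype(str) + ":" + (tra["start2"] // bin_size).astype(int).astype(str)
    tra["pair"] = [
        "--".join(sorted([a, b])) for a, b in zip(tra["w1"], tra["w2"])
    ]
    group_cols = ["pair"] + ([arm_column] if arm_column else [])
    counts = (
        tra.drop_duplicates(subset=group_cols + ["sample"])
        .groupby(group_cols).size().rename("n_tumors").reset_index()
    )
    return counts[counts["n_tumors"] >= min_tumors].sort_values(
        "n_tumors", ascending=False).reset_index(drop=True)


def tier_svs(svs: pd.DataFrame, tumors: list[str]) -> pd.Series:
    """Temporal tiers for SVs of one case by cross-tumor sharing of the
    SV family id (``name`` column): same semantics as mutation tiering."""
    sub = svs[svs["sample"].isin(tumors)]
    carriers = sub.groupby("name")["sample"].nunique()
    n = len(tumors)
    tiers = pd.Series("intermediate", index=carriers.index, dtype=object)
    tiers[carriers == n] = "early"
    tiers[carriers == 1] = "late"
    return tiers
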