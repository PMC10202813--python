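"""Cohort file formats, sample manifests, and the cohort-level filters.

The on-disk layout is plain TSV/GMT/JSON throughout:

* manifest TSV — one row per sequenced tissue: ``sample_id, case_id, organ,
  compartment (tumor/AN/NAN/normal), purity, treatment_arm, assay_wes,
  assay_wgs, assay_rna``.
* mutations — MAF-like TSV, 1-based inclusive coordinates.
* SVs — BEDPE (0-based, half-open) with ``svtype`` and junction-homology
  length ``homlen`` columns.
* CNA — gene-level calls: ``gene, sample, call (amp/del/neutral), total_cn``
  plus a ``cohort`` column separating the autopsy cohort from comparators.
* expression — gene x sample count matrix TSV.
* gene sets — GMT.

Also implements the variant-support consensus filter, the tumor-purity
selection rule and TMB arithmetic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

MANIFEST_COLUMNS = [
    "sample_id", "case_id", "organ", "compartment", "purity",
    "treatment_arm", "assay_wes", "assay_wgs", "assay_rna",
]
MUTATION_COLUMNS = [
    "mutation_id", "case", "sample", "chrom", "pos", "ref", "alt",
    "t_alt_reads", "t_depth", "n_alt_reads", "gene",
    "trinucleotide_context", "class",
]
INDEL_COLUMNS = [
    "indel_id", "case", "sample", "chrom", "pos", "indel_type", "length",
    "base", "homopolymer_len", "repeat_count", "mh_len", "gene", "class",
]
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
    "strand1", "strand2", "sample", "svtype", "homlen",
]
CNA_COLUMNS = ["gene", "sample", "call", "total_cn", "cohort", "case"]


class FormatError(ValueError):
    """A cohort file violated its format contract."""


@dataclass
class CohortBundle:
    """All tables of one loaded (or simulated) cohort, joined on sample_id."""

    manifest: pd.DataFrame
    mutations: pd.DataFrame
    indels: pd.DataFrame = None
    svs: pd.DataFrame = None
    cna: pd.DataFrame = None
    expression: pd.DataFrame = None          # genes x samples counts
    gene_sets: dict = field(default_factory=dict)

    def tumors_of_case(self, case_id: str) -> list[str]:
        m = self.manifest
        sel = m[(m.case_id == case_id) & (m.compartment == "tumor")]
        return sorted(sel.sample_id)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    if manifest["sample_id"].duplicated().any():
        dup = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id in manifest: {dup}")
    bad = set(manifest["compartment"]) - {"tumor", "AN", "NAN", "normal"}
    if bad:
        raise FormatError(f"unknown compartment labels: {sorted(bad)}")
    return manifest


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line with <3 fields in {path}: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, name] + list(sets[name])) + "\n")


def _read_tsv(path, required, name):
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{name} file {path} missing columns {missing}")
    return df


def load_cohort(directory, expression: bool = True) -> CohortBundle:
    """Load a cohort written by :func:`write_cohort` (or hand-assembled).

    Unknown sample_ids in data files are reported via the returned bundle's
    manifest join; coordinate sanity is enforced here.
    """
    d = Path(directory)
    manifest = validate_manifest(_read_tsv(d / "manifest.tsv", MANIFEST_COLUMNS[:4], "manifest"))
    muts = _read_tsv(d / "mutations.tsv", MUTATION_COLUMNS, "mutations")
    if (muts["pos"] < 1).any():
        raise FormatError("mutations.tsv: MAF-like pos must be 1-based (>=1)")
    indels = None
    if (d / "indels.tsv").exists():
        indels = _read_tsv(d / "indels.tsv", INDEL_COLUMNS, "indels")
        indels["base"] = indels["base"].fillna("")
    svs = None
    if (d / "svs.bedpe").exists():
        svs = pd.read_csv(d / "svs.bedpe", sep="\t")
        missing = [c for c in BEDPE_COLUMNS if c not in svs.columns]
        if missing:
            raise FormatError(f"svs.bedpe missing columns {missing}")
        if "gene" in svs.columns:
            svs["gene"] = svs["gene"].fillna("")
        if (svs[["start1", "start2"]] < 0).any().any():
            raise FormatError("svs.bedpe: negative start coordinate")
        if (svs["end1"] < svs["start1"]).any() or (svs["end2"] < svs["start2"]).any():
            raise FormatError("svs.bedpe: end < start")
    cna = None
    if (d / "cna.tsv").exists():
        cna = _read_tsv(d / "cna.tsv", CNA_COLUMNS[:4], "cna")
    expr = None
    if expression and (d / "expression.tsv").exists():
        expr = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    gene_sets = {}
    if (d / "gene_sets.gmt").exists():
        gene_sets = read_gmt(d / "gene_sets.gmt")
    known = set(manifest["sample_id"])
    unknown = sorted(set(muts["sample"]) - known)
    if unknown:
        warnings.warn(f"mutations.tsv references sample_ids absent from the "
                      f"manifest: {unknown[:5]}{'...' if len(unknown) > 5 else ''}")
    return CohortBundle(manifest=manifest, mutations=muts, indels=indels,
                        svs=svs, cna=cna, expression=expr, gene_sets=gene_sets)


def write_cohort(bundle: CohortBundle, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.manifest.to_csv(d / "manifest.tsv", sep="\t", index=False)
    bundle.mutations.to_csv(d / "mutations.tsv", sep="\t", index=False)
    if bundle.indels is not None:
        bundle.indels.to_csv(d / "indels.tsv", sep="\t", index=False)
    if bundle.svs is not None:
        bundle.svs.to_csv(d / "svs.bedpe", sep="\t", index=False)
    if bundle.cna is not None:
        bundle.cna.to_csv(d / "cna.tsv", sep="\t", index=False)
    if bundle.expression is not None:
        bundle.expression.to_csv(d / "expression.tsv", sep="\t")
    if bundle.gene_sets:
        write_gmt(bundle.gene_sets, d / "gene_sets.gmt")


def consensus_filter_calls(call_sets: list[pd.DataFrame], min_callers: int = 2,
                           min_t_reads: int = 5, max_n_reads: int = 0,
                           key_cols=("chrom", "pos", "ref", "alt")) -> pd.DataFrame:
    """Keep events called by >= ``min_callers`` callers with sufficient
    tumor support and at most ``max_n_reads`` reads in the matched normal.

    Events are keyed by ``key_cols`` across callers; read support is taken
    from the first caller listing the event. Raising ``min_callers`` never
    adds events (monotone).
    """
    if min_callers > len(call_sets):
        raise ValueError(
            f"min_callers={min_callers} exceeds the {len(call_sets)} call sets")
    key_cols = list(key_cols)
    keyed = [df.drop_duplicates(subset=key_cols) for df in call_sets]
    counts = pd.concat([df[key_cols] for df in keyed], ignore_index=True)
    support = counts.groupby(key_cols, sort=False).size()
    merged = pd.concat(keyed, ignore_index=True).drop_duplicates(subset=key_cols)
    n_callers = merged.set_index(key_cols).index.map(support)
    merged = merged.assign(n_callers=n_callers.values if hasattr(n_callers, "values") else n_callers)
    keep = (
        (merged["n_callers"] >= min_callers)
        & (merged["t_alt_reads"] >= min_t_reads)
        & (merged["n_alt_reads"] <= max_n_reads)
    )
    return merged.loc[keep].drop(columns="n_callers").reset_index(drop=True)


def filter_samples_by_purity(manifest: pd.DataFrame, min_purity: float = 0.30) -> pd.DataFrame:
    """Retain tumor samples with purity strictly above ``min_purity``.

    Non-tumor compartments (AN/NAN/normal) are never dropped; the rule models
    the histopathology-stage tissue selection, which only applies to tumors.
    """
    is_tumor = manifest["compartment"] == "tumor"
    keep = ~is_tumor | (manifest["purity"] > min_purity)
    return manifest.loc[keep].reset_index(drop=True)


def compute_tmb(n_mutations: int, footprint_mb: float) -> float:
    """Mutations per callable megabase."""
    if footprint_mb <= 0:
        raise ValueError("footprint_mb must be > 0")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    return n_mutations / footprint_mb


def lookup_context(fasta_path, chrom: str, pos: int) -> str:
    """Trinucleotide context around a 1-based position from a FASTA file.

    Optional convenience for tables that do not carry context strings;
    requires the pyfaidx package at call time.
    """
    import pyfaidx

    fa = pyfaidx.Fasta(str(fasta_path))
    return str(fa[chrom][pos - 2:pos + 1]).upper()


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
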