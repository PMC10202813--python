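"""Synthetic multi-organ autopsy cohort generator with full ground truth.

Emulates the data shape of a rapid-autopsy melanoma study: ~11 cases, each
with tumors in several organs plus adjacent-normal (AN) and non-adjacent
normal (NAN) tissues; patient-matched pre/post comparator cohorts for two
therapy arms and a large therapy-naive comparator. Per case, a random clone
tree places somatic mutations on trunk (early), internal-branch
(intermediate) and leaf (late) edges; each tier draws its trinucleotide
channels from a tier- and arm-dependent mixture of reference signatures.
VAFs follow purity, local copy number, multiplicity and cancer cell
fraction with binomial read sampling. Structural variants carry
junction-homology lengths drawn per true repair mechanism (so the
homology-bin classifier's confusion matrix is diagonal by construction).
Bulk expression is a linear count-space mixture: tumor program weighted by
purity plus the host organ's normal profile weighted by 1 - purity; AN
tissue carries at most 10% tumor program, NAN none.

All randomness flows from one root seed through named substreams, so any
artifact regenerates identically in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ramscape import channels as ch
from ramscape import phylo
from ramscape.io import CohortBundle
from ramscape.rng import substream
from ramscape.signatures import SignatureCatalog

ORGANS = ["brain", "lung", "liver", "LN", "adrenal", "ST"]
ARMS = ["MAPKi", "ICB", "MAPKi+ICB"]

AMP_GENES = ["BRAF", "TERT", "KEL", "MGAM", "RELN", "SETD1B", "CREB3L2", "RAD51B"]
DEL_GENES = ["CDKN2A", "B2M", "JAK2", "CD274", "SPRED1", "BRCA1"]
NULL_CNA_GENES = [f"CNULL{i:02d}" for i in range(1, 17)]
CNA_GENES = AMP_GENES + DEL_GENES + NULL_CNA_GENES

SBS_SIGNATURES = ["SBS-UV1", "SBS-UV2", "SBS-CLK", "SBS-HRD", "SBS-MMR"]

DEFAULT_TIER_EXPOSURES = {
    "MAPKi": {
        "early": {"SBS-UV1": 0.60, "SBS-UV2": 0.30, "SBS-CLK": 0.10},
        "intermediate": {"SBS-UV1": 0.50, "SBS-UV2": 0.30, "SBS-CLK": 0.20},
        "late": {"SBS-HRD": 0.45, "SBS-MMR": 0.25, "SBS-CLK": 0.30},
    },
    "ICB": {
        "early": {"SBS-UV1": 0.60, "SBS-UV2": 0.30, "SBS-CLK": 0.10},
        "intermediate": {"SBS-UV1": 0.50, "SBS-UV2": 0.30, "SBS-CLK": 0.20},
        "late": {"SBS-CLK": 0.40, "SBS-HRD": 0.30, "SBS-MMR": 0.30},
    },
    "MAPKi+ICB": {
        "early": {"SBS-UV1": 0.60, "SBS-UV2": 0.30, "SBS-CLK": 0.10},
        "intermediate": {"SBS-UV1": 0.50, "SBS-UV2": 0.30, "SBS-CLK": 0.20},
        "late": {"SBS-HRD": 0.40, "SBS-MMR": 0.30, "SBS-CLK": 0.30},
    },
}

# per-tier cancer cell fraction distributions (beta mean, concentration);
# early mutations are strictly clonal
DEFAULT_TIER_CCF = {
    "early": (1.0, None),
    "intermediate": (0.90, 40.0),
    "late": (0.65, 25.0),
}

DEFAULT_SV_CLASS_MIX = {
    ("non-clustered", "tra"): 0.62,
    ("non-clustered", "del"): 0.16,
    ("non-clustered", "inv"): 0.12,
    ("non-clustered", "dup"): 0.04,
    ("clustered", "del"): 0.02,
    ("clustered", "inv"): 0.02,
    ("clustered", "tra"): 0.02,
}

DEFAULT_REPAIR_MIX = {
    "early": {"NHEJ": 0.76, "alt-NHEJ": 0.18, "HRR": 0.06},
    "intermediate": {"NHEJ": 0.60, "alt-NHEJ": 0.30, "HRR": 0.10},
    "late": {"NHEJ": 0.55, "alt-NHEJ": 0.35, "HRR": 0.10},
}

SV_RECURRENT_GENES = [f"SVREC{i}" for i in range(1, 6)]
SV_RARE_GENES = [f"SVRARE{i}" for i in range(1, 6)]


@dataclass
class SimulationConfig:
    """All dials of the synthetic cohort; defaults mirror the study design."""

    n_cases: int = 11
    organs_per_case: int = 3
    tumors_per_organ: int = 2
    depth: float = 217.0
    purity_range: tuple = (0.40, 0.95)
    tier_mutation_counts: dict = field(default_factory=lambda: {
        "early": 400, "intermediate": 200, "late": 150})
    tier_exposures: dict = field(default_factory=lambda: DEFAULT_TIER_EXPOSURES)
    tier_ccf: dict = field(default_factory=lambda: dict(DEFAULT_TIER_CCF))
    indels_per_tumor: int = 30
    cna_freqs: pd.DataFrame | None = None   # columns: gene, event, cohort, prob
    n_naive: int = 300
    n_mapki_pairs: int = 28
    n_icb_pairs: int = 7
    sv_tier_counts: dict = field(default_factory=lambda: {
        "early": 60, "intermediate": 30, "late": 40})
    sv_class_mix: dict = field(default_factory=lambda: dict(DEFAULT_SV_CLASS_MIX))
    repair_mix: dict = field(default_factory=lambda: {
        t: dict(v) for t, v in DEFAULT_REPAIR_MIX.items()})
    hrr_geom_p: float = 0.3
    n_genes: int = 2000
    program_size: int = 50
    program_log2fc: float = 2.0
    n_archetypes: int = 12
    archetype_set_size: int = 20
    archetype_log2fc: float = 2.5
    archetype_mix: dict | None = None       # compartment -> {name: prob}
    organ_mutation_bias: dict | None = None  # organ -> genes mutated clonally there
    library_size: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must lie within (0, 1]")
        for arm, tiers in self.tier_exposures.items():
            for tier, mix in tiers.items():
                s = sum(mix.values())
                if abs(s - 1.0) > 1e-9:
                    raise ValueError(
                        f"exposure mix for {arm}/{tier} sums to {s}, not 1")
        for tier, mix in self.repair_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"repair mix for {tier} does not sum to 1")
        if abs(sum(self.sv_class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("sv_class_mix does not sum to 1")
        if min(self.tier_mutation_counts.values()) < 0:
            raise ValueError("tier mutation counts must be >= 0")


def default_cna_freqs(n_implant_amp: int = 8, n_implant_del: int = 6,
                      ram_freq: float = 0.6, base_freq: float = 0.1) -> pd.DataFrame:
    """Per-gene event probabilities per cohort: implanted genes are frequent
    in the autopsy cohort and in post-treatment tumors, rare elsewhere."""
    rows = []
    amp_impl = AMP_GENES[:n_implant_amp]
    del_impl = DEL_GENES[:n_implant_del]
    for gene in CNA_GENES:
        for event in ("amp", "del"):
            implanted = (gene in amp_impl and event == "amp") or \
                        (gene in del_impl and event == "del")
            other = gene in AMP_GENES or gene in DEL_GENES
            p_bg = 0.0 if (other and not implanted) else base_freq
            rows.append({"gene": gene, "event": event,
                         "ram": ram_freq if implanted else p_bg,
                         "naive": p_bg,
                         "mapki_pre": p_bg,
                         "mapki_post": (ram_freq if (implanted and event == "amp")
                                        else p_bg),
                         "icb_pre": p_bg,
                         "icb_post": (ram_freq if (implanted and event == "del")
                                      else p_bg)})
    long = pd.DataFrame(rows).melt(id_vars=["gene", "event"],
                                   var_name="cohort", value_name="prob")
    return long


# --- reference catalogs ------------------------------------------------------

def make_signature_catalog(space: str = "SBS96", names=None,
                           orthogonal: bool = False, peak_channels: int = 12,
                           peak_mass: float = 0.9, seed: int = 0) -> SignatureCatalog:
    """Column-stochastic synthetic signature catalog.

    Each signature concentrates ``peak_mass`` on its own set of peak
    channels (disjoint consecutive blocks when ``orthogonal``, with zero
    mass elsewhere so pairwise cosines are exactly 0). Seeded and
    regenerable byte-identically.
    """
    channels = ch.CHANNEL_SPACES[space]
    n = len(channels)
    if names is None:
        names = SBS_SIGNATURES if space == "SBS96" else [
            f"{space}-S{i+1}" for i in range(4)]
    k = len(names)
    if orthogonal and k > n:
        raise ValueError("cannot build more orthogonal signatures than channels")
    rng = substream(seed, f"catalog:{space}:{int(orthogonal)}")
    profiles = np.zeros((n, k))
    if orthogonal:
        block = n // k
        for j in range(k):
            idx = np.arange(j * block, (j + 1) * block if j < k - 1 else n)
            profiles[idx, j] = rng.dirichlet(np.ones(len(idx)))
    else:
        for j in range(k):
            peaks = rng.choice(n, size=min(peak_channels, n), replace=False)
            profiles[peaks, j] = peak_mass * rng.dirichlet(np.ones(len(peaks)))
            rest = np.setdiff1d(np.arange(n), peaks)
            profiles[rest, j] = (1 - peak_mass) * rng.dirichlet(np.ones(len(rest)))
    return SignatureCatalog(space=space,
                            profiles=pd.DataFrame(profiles, index=channels,
                                                  columns=list(names)))


def make_rs_catalog(seed: int = 0) -> SignatureCatalog:
    """Synthetic RS32 catalog whose RS2-like column concentrates on large
    (>100 kb) non-clustered deletions/inversions and translocations."""
    channels = ch.RS32_CHANNELS
    rng = substream(seed, "catalog:RS32")
    names = ["RS2-like", "RS4-like", "RS-other"]
    profiles = pd.DataFrame(0.0, index=channels, columns=names)
    rs2 = [c for c in channels if c.startswith("non-clustered") and (
        "100kb-1Mb" in c or "1-10Mb" in c or ">10Mb" in c or c.endswith("tra"))
        and ("del" in c or "inv" in c or "tra" in c)]
    rs4 = [c for c in channels if "del" in c and ("1-10kb" in c or "10-100kb" in c)]
    rest = [c for c in channels if c not in rs2 + rs4]
    profiles.loc[rs2, "RS2-like"] = rng.dirichlet(np.ones(len(rs2)))
    profiles.loc[rs4, "RS4-like"] = rng.dirichlet(np.ones(len(rs4)))
    profiles.loc[rest, "RS-other"] = rng.dirichlet(np.ones(len(rest)))
    return SignatureCatalog(space="RS32", profiles=profiles)


def make_gene_sets(config: SimulationConfig) -> dict[str, list[str]]:
    """Named gene collections wired to the generator's implanted programs."""
    sets = {}
    for organ in ORGANS:
        sets[f"marker_{organ}"] = [f"MK_{organ}_{i}" for i in range(5)]
        sets[f"program_{organ}"] = [f"TP_{organ}_{i}"
                                    for i in range(config.program_size)]
    for a in range(config.n_archetypes):
        sets[f"archetype_{a+1:02d}"] = [f"ARC{a+1:02d}_{i}"
                                        for i in range(config.archetype_set_size)]
    sets["t_cell_exhaustion"] = [f"EXH_{i}" for i in range(20)]
    sets["type2_immunity"] = [f"TY2_{i}" for i in range(20)]
    return sets


def make_reference_catalogs(config: SimulationConfig,
                            space: str = "SBS96") -> tuple[SignatureCatalog, dict]:
    """The signature catalog and gene-set collection a run needs."""
    if space not in ch.CHANNEL_SPACES:
        raise ValueError(f"unknown channel space {space!r}")
    if space == "RS32":
        catalog = make_rs_catalog(seed=config.seed)
    else:
        catalog = make_signature_catalog(space=space, seed=config.seed)
    return catalog, make_gene_sets(config)


# --- cohort simulation -------------------------------------------------------

def _draw_ccf(tier: str, tier_ccf: dict, rng) -> float:
    mean, conc = tier_ccf[tier]
    if conc is None:
        return float(mean)
    a, b = mean * conc, (1 - mean) * conc
    return float(rng.beta(a, b))


def _channel_fields(channel: str):
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, five + ref + three


def _case_arm(i: int, n_cases: int) -> str:
    # mirror the study's 4 / 4 / 3 arm split, cycling beyond 11 cases
    pattern = (["MAPKi"] * 4 + ["ICB"] * 4 + ["MAPKi+ICB"] * 3)
    return pattern[i % len(pattern)]


def simulate_cohort(config: SimulationConfig,
                    catalog: SignatureCatalog | None = None) -> tuple[CohortBundle, dict]:
    """Generate a cohort bundle plus its ground truth.

    Raises ``ValueError`` when the configured exposure mixtures name
    signatures absent from the catalog.
    """
    if catalog is None:
        catalog = make_signature_catalog(seed=config.seed)
    for arm, tiers in config.tier_exposures.items():
        for tier, mix in tiers.items():
            unknown = set(mix) - set(catalog.names)
            if unknown:
                raise ValueError(
                    f"exposure mix {arm}/{tier} names unknown signatures {sorted(unknown)}")
    seed = config.seed
    truth = {"tiers": {}, "sv_tiers": {}, "exposures": {}, "repair": {},
             "organ_programs": {}, "archetype": {}, "trees": {},
             "cna_implants": {}, "lr_pairs": [], "ccf": {},
             "an_tumor_fraction": {}}

    manifest = _simulate_manifest(config)
    cases = sorted(manifest["case_id"].unique())
    arm_of_case = manifest.drop_duplicates("case_id").set_index("case_id")["treatment_arm"]

    mut_rows, indel_rows, sv_rows = [], [], []
    cna_rows = []
    for case in cases:
        tumors = sorted(manifest[(manifest.case_id == case)
                                 & (manifest.compartment == "tumor")]["sample_id"])
        arm = arm_of_case[case]
        purity = manifest.set_index("sample_id")["purity"]
        topo = _case_tree(case, len(tumors), seed)
        truth["trees"][case] = f"({phylo._newick(topo, tumors)},normal);"
        clades = _clades(topo, tumors)
        amp_in_case = _case_cna(case, config, seed, tumors, cna_rows, truth)
        organ_of = manifest.set_index("sample_id")["organ"]
        _case_mutations(case, config, catalog, arm, tumors, clades, purity,
                        amp_in_case, seed, mut_rows, truth, organ_of)
        _case_indels(case, config, tumors, seed, indel_rows)
        _case_svs(case, config, tumors, clades, seed, sv_rows, truth)

    _comparator_cna(config, seed, cna_rows, truth)

    mutations = pd.DataFrame(mut_rows)
    indels = pd.DataFrame(indel_rows)
    svs = pd.DataFrame(sv_rows)
    cna = pd.DataFrame(cna_rows)
    gene_sets = make_gene_sets(config)
    expression = _simulate_expression(config, manifest, gene_sets, seed, truth)

    bundle = CohortBundle(manifest=manifest, mutations=mutations,
                          indels=indels, svs=svs, cna=cna,
                          expression=expression, gene_sets=gene_sets)
    return bundle, truth


def _simulate_manifest(config: SimulationConfig) -> pd.DataFrame:
    rng = substream(config.seed, "manifest")
    lo, hi = config.purity_range
    rows = []
    for i in range(config.n_cases):
        case = f"RAM{i+1:02d}"
        arm = _case_arm(i, config.n_cases)
        organs = sorted(rng.choice(ORGANS, size=config.organs_per_case,
                                   replace=False))
        for organ in organs:
            for t in range(config.tumors_per_organ):
                rows.append({
                    "sample_id": f"{case}_{organ}_T{t+1}", "case_id": case,
                    "organ": organ, "compartment": "tumor",
                    "purity": round(float(rng.uniform(lo, hi)), 4),
                    "treatment_arm": arm, "assay_wes": True,
                    "assay_wgs": True, "assay_rna": True,
                })
            for comp in ("AN", "NAN"):
                rows.append({
                    "sample_id": f"{case}_{organ}_{comp}", "case_id": case,
                    "organ": organ, "compartment": comp, "purity": np.nan,
                    "treatment_arm": arm, "assay_wes": False,
                    "assay_wgs": False, "assay_rna": True,
                })
    return pd.DataFrame(rows)


def _case_tree(case: str, n_tumors: int, seed: int):
    rng = substream(seed, f"tree:{case}")
    return phylo._random_topology(n_tumors, rng)


def _clades(topo, tumors) -> list[list[str]]:
    """Proper, non-trivial clades (internal edges) of the case tree."""
    clades = []

    def walk(node):
        if isinstance(node, (int, np.integer)):
            return [node]
        leaves = walk(node[0]) + walk(node[1])
        if 1 < len(leaves) < len(tumors):
            clades.append(sorted(leaves))
        return leaves

    walk(topo)
    return [[tumors[i] for i in c] for c in clades]


def _gene_probs(freqs: pd.DataFrame, cohort: str) -> pd.DataFrame:
    sub = freqs[freqs.cohort == cohort]
    return sub.pivot_table(index="gene", columns="event", values="prob",
                           fill_value=0.0).reindex(columns=["amp", "del"],
                                                   fill_value=0.0)


def _case_cna(case, config, seed, tumors, cna_rows, truth):
    rng = substream(seed, f"cna:{case}")
    freqs = config.cna_freqs if config.cna_freqs is not None else default_cna_freqs()
    probs = _gene_probs(freqs, "ram")
    amp_in_case = {}
    for gene in probs.index:
        amp_hit = rng.random() < probs.loc[gene, "amp"]
        del_hit = rng.random() < probs.loc[gene, "del"]
        if amp_hit:  # amplification takes precedence over a co-drawn deletion
            call, total_cn = "amp", int(rng.integers(4, 9))
            amp_in_case[gene] = total_cn
        elif del_hit:
            call, total_cn = "del", int(rng.integers(0, 2))
        else:
            call, total_cn = "neutral", 2
        for s in tumors:
            cna_rows.append({"gene": gene, "sample": s, "call": call,
                             "total_cn": total_cn, "cohort": "ram", "case": case})
    return amp_in_case


def _comparator_cna(config, seed, cna_rows, truth):
    rng = substream(seed, "cna:comparators")
    freqs = config.cna_freqs if config.cna_freqs is not None else default_cna_freqs()
    sizes = {"naive": config.n_naive, "mapki_pre": config.n_mapki_pairs,
             "mapki_post": config.n_mapki_pairs, "icb_pre": config.n_icb_pairs,
             "icb_post": config.n_icb_pairs}
    for cohort, n in sizes.items():
        probs = _gene_probs(freqs, cohort)
        for gene in probs.index:
            amp_hits = rng.random(n) < probs.loc[gene, "amp"]
            del_hits = rng.random(n) < probs.loc[gene, "del"]
            for j in range(n):
                call = "amp" if amp_hits[j] else ("del" if del_hits[j] else "neutral")
                cna_rows.append({
                    "gene": gene, "sample": f"{cohort}_{j+1:03d}",
                    "call": call,
                    "total_cn": 4 if call == "amp" else (1 if call == "del" else 2),
                    "cohort": cohort, "case": f"{cohort.split('_')[0]}_{j+1:03d}"})
    freqs_w = freqs.pivot_table(index=["gene", "event"], columns="cohort",
                                values="prob").reset_index()
    truth["cna_implants"] = {
        "ram_vs_naive": sorted(freqs_w.loc[freqs_w.ram > freqs_w.naive, "gene"].unique()),
        "icb_post_vs_pre": sorted(
            freqs_w.loc[freqs_w.icb_post > 2 * freqs_w.icb_pre, "gene"].unique()),
        "mapki_post_vs_pre": sorted(
            freqs_w.loc[freqs_w.mapki_post > freqs_w.mapki_pre, "gene"].unique()),
    }


def _case_mutations(case, config, catalog, arm, tumors, clades, purity,
                    amp_in_case, seed, mut_rows, truth, organ_of=None):
    rng = substream(seed, f"muts:{case}")
    P = catalog.profiles
    exposures = config.tier_exposures[arm]
    truth["exposures"][case] = {t: dict(m) for t, m in exposures.items()}
    counter = 0
    amp_genes = sorted(amp_in_case)

    def emit(tier, carriers):
        nonlocal counter
        mix = exposures.get(tier)
        if mix is None:
            return
        sig_names = sorted(mix)
        probs = np.array([mix[s] for s in sig_names])
        n = config.tier_mutation_counts.get(tier, 0)
        if tier == "intermediate" and not clades:
            return
        for _ in range(n):
            counter += 1
            mid = f"{case}:m{counter:05d}"
            sig = sig_names[rng.choice(len(sig_names), p=probs)]
            channel = ch.SBS96_CHANNELS[
                rng.choice(96, p=P[sig].to_numpy())]
            ref, alt, ctx = _channel_fields(channel)
            if rng.random() < 0.5:  # place on either strand
                ref, alt, ctx = ch.COMPLEMENT[ref], ch.COMPLEMENT[alt], ch.revcomp(ctx)
            ccf = _draw_ccf(tier, config.tier_ccf, rng)
            if amp_genes and rng.random() < 0.05:
                gene = amp_genes[rng.integers(len(amp_genes))]
                cnt = amp_in_case[gene]
                m = int(rng.integers(1, cnt + 1))
            else:
                gene = f"G{rng.integers(1, 5001):04d}"
                cnt, m = 2, 1
            klass = ["missense", "silent", "nonsense", "splice_site"][
                rng.choice(4, p=[0.55, 0.35, 0.05, 0.05])]
            chrom = f"chr{rng.integers(1, 23)}"
            pos = int(rng.integers(1, 2_000_000))
            truth["tiers"][mid] = tier
            truth["ccf"][mid] = ccf
            for s in carriers:
                rho = purity[s]
                vaf = rho * ccf * m / (rho * cnt + (1 - rho) * 2)
                depth = max(int(rng.poisson(config.depth)), 1)
                alt_reads = int(rng.binomial(depth, min(vaf, 1.0)))
                mut_rows.append({
                    "mutation_id": mid, "case": case, "sample": s,
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "t_alt_reads": alt_reads, "t_depth": depth,
                    "n_alt_reads": 0, "gene": gene,
                    "trinucleotide_context": ctx, "class": klass,
                })

    emit("early", tumors)
    if clades:
        per_clade = max(config.tier_mutation_counts.get("intermediate", 0)
                        // len(clades), 0)
        saved = config.tier_mutation_counts.get("intermediate", 0)
        for clade in clades:
            config.tier_mutation_counts["intermediate"] = per_clade
            emit("intermediate", clade)
        config.tier_mutation_counts["intermediate"] = saved
    for t in tumors:
        emit("late", [t])

    # implanted organ-preferential mutations: clonal in every tumor of the
    # biased organ, absent elsewhere in the case
    if config.organ_mutation_bias and organ_of is not None:
        truth.setdefault("organ_biased_genes", {
            o: sorted(g) for o, g in config.organ_mutation_bias.items()})
        for organ in sorted(config.organ_mutation_bias):
            carriers = [t for t in tumors if organ_of[t] == organ]
            if not carriers:
                continue
            n_carriers = len(carriers)
            tier = ("early" if n_carriers == len(tumors)
                    else "late" if n_carriers == 1 else "intermediate")
            for gene in sorted(config.organ_mutation_bias[organ]):
                counter += 1
                mid = f"{case}:m{counter:05d}"
                truth["tiers"][mid] = tier
                truth["ccf"][mid] = 1.0
                chrom = f"chr{rng.integers(1, 23)}"
                pos = int(rng.integers(1, 2_000_000))
                for s in carriers:
                    rho = purity[s]
                    vaf = rho / (rho * 2 + (1 - rho) * 2)
                    depth = max(int(rng.poisson(config.depth)), 1)
                    alt_reads = int(rng.binomial(depth, min(vaf, 1.0)))
                    mut_rows.append({
                        "mutation_id": mid, "case": case, "sample": s,
                        "chrom": chrom, "pos": pos, "ref": "C", "alt": "T",
                        "t_alt_reads": alt_reads, "t_depth": depth,
                        "n_alt_reads": 0, "gene": gene,
                        "trinucleotide_context": "ACA", "class": "missense",
                    })


def _case_indels(case, config, tumors, seed, indel_rows):
    rng = substream(seed, f"indels:{case}")
    counter = 0
    for s in tumors:
        for _ in range(config.indels_per_tumor):
            counter += 1
            is_del = rng.random() < 0.55
            if rng.random() < 0.7:
                length, base = 1, ("C" if rng.random() < 0.5 else "T")
                hp = int(rng.integers(1, 8))
                rep, mh = 0, 0
            else:
                length = int(rng.integers(2, 7))
                base = ""
                hp = 0
                if is_del and rng.random() < 0.4:
                    rep, mh = 0, int(rng.integers(1, length))
                else:
                    rep, mh = int(rng.integers(1, 7)), 0
            indel_rows.append({
                "indel_id": f"{case}:id{counter:04d}", "case": case,
                "sample": s, "chrom": f"chr{rng.integers(1, 23)}",
                "pos": int(rng.integers(1, 2_000_000)),
                "indel_type": "del" if is_del else "ins", "length": length,
                "base": base, "homopolymer_len": hp, "repeat_count": rep,
                "mh_len": mh, "gene": f"G{rng.integers(1, 5001):04d}",
                "class": "frameshift" if length % 3 else "inframe",
            })


def _draw_homlen(mech: str, config, rng) -> int:
    if mech == "NHEJ":
        return int(rng.integers(0, 2))
    if mech == "alt-NHEJ":
        return int(rng.integers(2, 7))
    return 7 + int(rng.geometric(config.hrr_geom_p)) - 1


def _case_svs(case, config, tumors, clades, seed, sv_rows, truth):
    rng = substream(seed, f"svs:{case}")
    classes = sorted(config.sv_class_mix)
    class_p = np.array([config.sv_class_mix[c] for c in classes])
    hotspot_chrom = f"chr{rng.integers(1, 23)}"
    hotspot_start = int(rng.integers(10_000_000, 100_000_000))
    counter = 0

    def emit(tier, carriers):
        nonlocal counter
        n = config.sv_tier_counts.get(tier, 0)
        if tier == "intermediate" and not clades:
            return
        mech_names = sorted(config.repair_mix[tier])
        mech_p = np.array([config.repair_mix[tier][m] for m in mech_names])
        for _ in range(n):
            counter += 1
            name = f"{case}:sv{counter:05d}"
            clus, svtype = classes[rng.choice(len(classes), p=class_p)]
            mech = mech_names[rng.choice(len(mech_names), p=mech_p)]
            homlen = _draw_homlen(mech, config, rng)
            if clus == "clustered":
                chrom1 = chrom2 = hotspot_chrom
                p1 = hotspot_start + int(rng.integers(0, 400_000))
                p2 = p1 + int(rng.integers(5_000, 90_000))
            elif svtype == "tra":
                chrom1 = f"chr{rng.integers(1, 23)}"
                chrom2 = f"chr{(rng.integers(1, 23) % 22) + 1}"
                p1 = int(rng.integers(1, 150_000_000))
                p2 = int(rng.integers(1, 150_000_000))
            else:
                chrom1 = chrom2 = f"chr{rng.integers(1, 23)}"
                size = int(10 ** rng.uniform(4.1, 7.0))
                p1 = int(rng.integers(1, 150_000_000))
                p2 = p1 + size
            gene = ""
            truth["repair"][name] = mech
            truth["sv_tiers"][name] = tier
            for s in carriers:
                sv_rows.append({
                    "chrom1": chrom1, "start1": p1, "end1": p1 + 1,
                    "chrom2": chrom2, "start2": p2, "end2": p2 + 1,
                    "name": name, "score": ".", "strand1": "+", "strand2": "-",
                    "sample": s, "svtype": svtype, "homlen": homlen,
                    "gene": gene,
                })

    emit("early", tumors)
    if clades:
        saved = config.sv_tier_counts.get("intermediate", 0)
        per_clade = max(saved // len(clades), 0)
        for clade in clades:
            config.sv_tier_counts["intermediate"] = per_clade
            emit("intermediate", clade)
        config.sv_tier_counts["intermediate"] = saved
    for t in tumors:
        emit("late", [t])

    # implant per-tumor gene-overlap recurrence: recurrent genes are hit by
    # some SV in ~65% of tumors, rare genes in ~20%
    row_idx = {t: [i for i, r in enumerate(sv_rows) if r["sample"] == t]
               for t in tumors}
    for t in tumors:
        rows = row_idx[t]
        for gene, p in ([(g, 0.65) for g in SV_RECURRENT_GENES]
                        + [(g, 0.20) for g in SV_RARE_GENES]):
            if rows and rng.random() < p:
                sv_rows[rows[int(rng.integers(len(rows)))]]["gene"] = gene


# --- expression --------------------------------------------------------------

def _archetype_of(sample_row, config, gene_sets, rng) -> str:
    names = sorted(n for n in gene_sets if n.startswith("archetype_"))
    mix = (config.archetype_mix or {}).get(sample_row.compartment)
    if mix:
        keys = sorted(mix)
        return keys[rng.choice(len(keys), p=np.array([mix[k] for k in keys]))]
    if sample_row.compartment == "tumor":
        # immune-desert-like archetype dominates tumor microenvironments
        return names[0] if rng.random() < 0.9 else names[4]
    organ_idx = ORGANS.index(sample_row.organ)
    return names[(organ_idx + 1) % len(names)]


def _simulate_expression(config, manifest, gene_sets, seed, truth):
    rng = substream(seed, "expression")
    genes = _gene_universe(config, gene_sets)
    n = len(genes)
    gi = {g: i for i, g in enumerate(genes)}
    base = rng.lognormal(mean=3.0, sigma=1.0, size=n)

    organ_normal = {}
    for organ in ORGANS:
        prof = base.copy()
        for g in gene_sets[f"marker_{organ}"]:
            prof[gi[g]] *= 2 ** 4
        organ_normal[organ] = prof / prof.sum()

    program_lfc = {}
    for organ in ORGANS:
        truth["organ_programs"][organ] = list(gene_sets[f"program_{organ}"])
    lr_ligands = [f"LG_{i}" for i in range(5)]
    lr_receptors = [f"RC_{i}" for i in range(5)]
    lr_organ = "liver"
    truth["lr_pairs"] = [{"organ": lr_organ, "ligand": l, "receptor": r,
                          "direction": "tumor->AN"}
                         for l, r in zip(lr_ligands, lr_receptors)]

    def tumor_profile(organ):
        prof = base.copy()
        for g in gene_sets[f"program_{organ}"]:
            prof[gi[g]] *= 2 ** config.program_log2fc
        for g in gene_sets["t_cell_exhaustion"] + gene_sets["type2_immunity"]:
            prof[gi[g]] *= 2 ** 1.5
        if organ == lr_organ:
            for g in lr_ligands:
                prof[gi[g]] *= 2 ** 3
        return prof / prof.sum()

    cols = {}
    for row in manifest.itertuples(index=False):
        arch = _archetype_of(row, config, gene_sets, rng)
        truth["archetype"][row.sample_id] = arch
        normal = organ_normal[row.organ]
        if row.compartment == "tumor":
            w = float(row.purity)
            frac = w * tumor_profile(row.organ) + (1 - w) * normal
        elif row.compartment == "AN":
            tf = float(rng.uniform(0.0, 0.10))
            truth["an_tumor_fraction"][row.sample_id] = tf
            prof_n = normal.copy()
            if row.organ == lr_organ:
                for g in lr_receptors:
                    prof_n[gi[g]] *= 2 ** 3
                prof_n = prof_n / prof_n.sum()
            frac = tf * tumor_profile(row.organ) + (1 - tf) * prof_n
        else:
            frac = normal.copy()
        for g in gene_sets[arch]:
            frac[gi[g]] *= 2 ** config.archetype_log2fc
        frac = frac / frac.sum()
        cols[row.sample_id] = rng.poisson(config.library_size * frac)
    return pd.DataFrame(cols, index=genes)


def _gene_universe(config, gene_sets) -> list[str]:
    special = []
    for name in sorted(gene_sets):
        special.extend(gene_sets[name])
    special.extend(f"LG_{i}" for i in range(5))
    special.extend(f"RC_{i}" for i in range(5))
    special = list(dict.fromkeys(special))
    n_bg = max(config.n_genes - len(special), 0)
    background = [f"BG_{i:04d}" for i in range(n_bg)]
    return special + background
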