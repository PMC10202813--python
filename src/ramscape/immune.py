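"""Immune-archetype assignment, program scoring, and tumor-macroenvironment
ligand-receptor crosstalk.

Each tissue sample is scored against a collection of immune-archetype gene
sets (12 pan-cancer archetypes in the study; synthetic sets in tests) with
the rank-based single-sample enrichment score and assigned the argmax
archetype (lexicographic tie-break). Ligand-receptor crosstalk between tumor
and adjacent-normal (AN) compartments uses a transparent product-of-means
strength with a compartment-label permutation null, then keeps only pairs
significant in tumor-AN but not in tumor-NAN of the same organ — the
AN-specific culling rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ramscape.rng import substream
from ramscape.transcriptome import ss_enrichment_score


def assign_archetypes(log2cpm: pd.DataFrame, archetype_sets: dict) -> pd.DataFrame:
    """Per-sample archetype enrichment scores and argmax label.

    Returns a table indexed by sample with one score column per archetype,
    plus ``label`` and a ``tie`` flag (exact score ties broken by
    lexicographically first archetype name).
    """
    if not archetype_sets:
        raise ValueError("archetype set collection is empty")
    names = sorted(archetype_sets)
    scores = {
        name: [ss_enrichment_score(log2cpm[s], archetype_sets[name])
               for s in log2cpm.columns]
        for name in names
    }
    out = pd.DataFrame(scores, index=log2cpm.columns)
    best = out.max(axis=1)
    labels, ties = [], []
    for sample in out.index:
        winners = [n for n in names if out.loc[sample, n] == best[sample]]
        labels.append(winners[0])
        ties.append(len(winners) > 1)
    out["label"] = labels
    out["tie"] = ties
    return out


def archetype_composition(assignments: pd.DataFrame,
                          manifest: pd.DataFrame) -> pd.DataFrame:
    """Archetype label fractions per (organ, compartment); rows sum to 1."""
    meta = manifest.set_index("sample_id")
    df = assignments.join(meta[["organ", "compartment"]])
    comp = (
        df.groupby(["organ", "compartment"])["label"]
        .value_counts(normalize=True).rename("fraction").reset_index()
    )
    return comp


def score_programs(log2cpm: pd.DataFrame, program_sets: dict,
                   manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Single-sample scores for expression programs (e.g., T-cell exhaustion,
    type-2 immunity), optionally annotated with organ/compartment."""
    rows = {
        name: [ss_enrichment_score(log2cpm[s], genes) for s in log2cpm.columns]
        for name, genes in program_sets.items()
    }
    out = pd.DataFrame(rows, index=log2cpm.columns)
    if manifest is not None:
        meta = manifest.set_index("sample_id")
        out = out.join(meta[["organ", "compartment"]])
    return out


def _eligible_organs(manifest: pd.DataFrame, min_pairs: int = 4,
                     min_cases: int = 3) -> list[str]:
    """Organs with >= min_pairs tumor-AN and tumor-NAN case pairs from
    >= min_cases distinct cases."""
    ok = []
    for organ, sub in manifest.groupby("organ"):
        cases_t = set(sub[sub.compartment == "tumor"].case_id)
        cases_an = set(sub[sub.compartment == "AN"].case_id)
        cases_nan = set(sub[sub.compartment == "NAN"].case_id)
        pairs_an = cases_t & cases_an
        pairs_nan = cases_t & cases_nan
        if (len(pairs_an) >= min_pairs and len(pairs_nan) >= min_pairs
                and len(pairs_an | pairs_nan) >= min_cases):
            ok.append(organ)
    return sorted(ok)


def _pair_strength(log2cpm, ligand, receptor, senders, receivers) -> float:
    lig = max(float(log2cpm.loc[ligand, senders].mean()), 0.0)
    rec = max(float(log2cpm.loc[receptor, receivers].mean()), 0.0)
    return lig * rec


def lr_crosstalk(log2cpm: pd.DataFrame, lr_database: pd.DataFrame,
                 manifest: pd.DataFrame, min_pairs: int = 4,
                 min_cases: int = 3, n_perm: int = 200, alpha: float = 0.05,
                 min_log2_effect: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """AN-specific ligand-receptor signalling per eligible organ.

    For each eligible organ and direction (tumor->AN and AN->tumor):
    strength = mean ligand log2CPM in the sender compartment x mean receptor
    log2CPM in the receiver compartment, both floored at 0. Significance
    permutes compartment labels among that organ's sender+receiver samples
    ``n_perm`` times, separately for the ligand's sender enrichment and the
    receptor's receiver enrichment; the pair's p is the larger of the two
    (signalling requires both partners to be compartment-specific), and each
    enrichment must additionally clear ``min_log2_effect`` — a fold floor
    that keeps small compositional shifts, inevitable in normalised bulk
    data, from registering as signalling. A pair
    is reported when significant (p < alpha) in the tumor-AN comparison but
    not in the tumor-NAN comparison of the same organ and direction.
    """
    organs = _eligible_organs(manifest, min_pairs=min_pairs, min_cases=min_cases)
    meta = manifest.set_index("sample_id")
    rows = []
    for organ in organs:
        sub = meta[(meta.organ == organ)]
        tum = [s for s in sub[sub.compartment == "tumor"].index if s in log2cpm.columns]
        an = [s for s in sub[sub.compartment == "AN"].index if s in log2cpm.columns]
        nan_ = [s for s in sub[sub.compartment == "NAN"].index if s in log2cpm.columns]
        rng = substream(seed, f"lr:{organ}")
        for _, lr in lr_database.iterrows():
            lig, rec = lr["ligand"], lr["receptor"]
            if lig not in log2cpm.index or rec not in log2cpm.index:
                continue
            for direction, senders, receivers in (
                    ("tumor->AN", tum, an), ("AN->tumor", an, tum)):
                alt_receivers = nan_ if receivers is an else receivers
                alt_senders = nan_ if senders is an else senders
                obs = _pair_strength(log2cpm, lig, rec, senders, receivers)
                p_an = _perm_p(log2cpm, lig, rec, senders, receivers,
                               n_perm, rng, min_log2_effect)
                p_nan = _perm_p(log2cpm, lig, rec, alt_senders, alt_receivers,
                                n_perm, rng, min_log2_effect)
                if p_an < alpha and p_nan >= alpha:
                    rows.append({
                        "organ": organ, "direction": direction,
                        "ligand": lig, "receptor": rec,
                        "strength": obs, "p_an": p_an, "p_nan": p_nan,
                    })
    return pd.DataFrame(rows, columns=["organ", "direction", "ligand",
                                       "receptor", "strength", "p_an", "p_nan"])


def _perm_p(log2cpm, ligand, receptor, senders, receivers,
            n_perm, rng, min_log2_effect=1.0) -> float:
    """max of the ligand's sender-enrichment and the receptor's
    receiver-enrichment label-permutation p-values; an enrichment below the
    log2 effect floor counts as non-significant outright."""
    n_s, n_r = len(senders), len(receivers)
    if n_s == 0 or n_r == 0:
        return 1.0
    pool = np.array(list(senders) + list(receivers))
    lig_vals = log2cpm.loc[ligand, pool].to_numpy(float)
    rec_vals = log2cpm.loc[receptor, pool].to_numpy(float)
    obs_lig = lig_vals[:n_s].mean()
    obs_rec = rec_vals[n_s:].mean()
    if (obs_lig - lig_vals[n_s:].mean() < min_log2_effect
            or obs_rec - rec_vals[:n_s].mean() < min_log2_effect):
        return 1.0
    ge_lig = ge_rec = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(pool))
        ge_lig += lig_vals[idx[:n_s]].mean() >= obs_lig
        ge_rec += rec_vals[idx[n_s:]].mean() >= obs_rec
    p_lig = (1 + ge_lig) / (1 + n_perm)
    p_rec = (1 + ge_rec) / (1 + n_perm)
    return float(max(p_lig, p_rec))
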