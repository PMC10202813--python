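"""Mutational spectra and sparse non-negative signature refitting.

A *spectrum* is a count vector over a fixed channel space (SBS96, ID83 or
RS32); a *catalog* holds reference signature profiles as a column-stochastic
channels x signatures matrix. Refitting finds non-negative exposures
minimising the Euclidean distance between the normalised spectrum and the
catalog reconstruction, then greedily prunes minor signatures (below a
proportion cutoff, default 0.06) as long as the reconstruction cosine
similarity drops by less than a tolerance (default 0.01) — the behaviour of
the standard refitting tools in this space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ramscape import channels as ch


@dataclass
class Spectrum:
    space: str                       # "SBS96" | "ID83" | "RS32"
    counts: np.ndarray               # aligned to channels.CHANNEL_SPACES[space]
    source: str = ""
    n_skipped: int = 0               # records dropped for ambiguous context

    @property
    def channels(self) -> list[str]:
        return ch.CHANNEL_SPACES[self.space]

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=self.channels, name=self.source)


@dataclass
class SignatureCatalog:
    space: str
    profiles: pd.DataFrame           # channels x signatures, columns sum to 1

    def __post_init__(self):
        expected = ch.CHANNEL_SPACES[self.space]
        if list(self.profiles.index) != expected:
            self.profiles = self.profiles.reindex(expected)
            if self.profiles.isna().any().any():
                raise ValueError("catalog channels do not match the space")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("catalog columns must each sum to 1")

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    @classmethod
    def read_tsv(cls, path, space: str) -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(space=space, profiles=df)

    def write_tsv(self, path) -> None:
        self.profiles.to_csv(path, sep="\t")


@dataclass
class ExposureVector:
    proportions: pd.Series           # indexed by signature name, sums to 1
    cosine: float                    # reconstruction cosine similarity
    n_mutations: float
    low_confidence: bool = False


def build_sbs96_spectrum(mutations: pd.DataFrame, source: str = "") -> Spectrum:
    """Bin SNVs into the 96 trinucleotide channels.

    Purine-reference records are reverse-complemented to the pyrimidine
    strand. Non-SNVs (len(ref) != 1 or len(alt) != 1) and records with
    ambiguous context bases are skipped and tallied in ``n_skipped``.
    """
    counts = np.zeros(96)
    skipped = 0
    for ref, alt, ctx in zip(mutations["ref"], mutations["alt"],
                             mutations["trinucleotide_context"]):
        ref, alt = str(ref), str(alt)
        if len(ref) != 1 or len(alt) != 1 or ref == alt:
            skipped += 1
            continue
        try:
            label = ch.sbs96_channel(ref, alt, str(ctx))
        except (KeyError, ValueError):
            skipped += 1
            continue
        counts[ch.SBS96_INDEX[label]] += 1
    return Spectrum("SBS96", counts, source=source, n_skipped=skipped)


def build_id_spectrum(indels: pd.DataFrame, source: str = "") -> Spectrum:
    """Bin indels into the 83 context channels.

    Expects the context summary columns carried in the indel table:
    ``indel_type, length, base, homopolymer_len, repeat_count, mh_len``.
    """
    required = {"indel_type", "length", "base", "homopolymer_len",
                "repeat_count", "mh_len"}
    missing = required - set(indels.columns)
    if missing:
        raise ValueError(f"indel table missing context columns: {sorted(missing)}")
    counts = np.zeros(83)
    skipped = 0
    for row in indels.itertuples(index=False):
        try:
            label = ch.id83_channel(
                row.indel_type, int(row.length), base=row.base,
                homopolymer_len=int(row.homopolymer_len),
                repeat_count=int(row.repeat_count), mh_len=int(row.mh_len))
        except (KeyError, ValueError):
            skipped += 1
            continue
        counts[ch.ID83_INDEX[label]] += 1
    return Spectrum("ID83", counts, source=source, n_skipped=skipped)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def refit_exposures(spectrum: Spectrum, catalog: SignatureCatalog,
                    prune_cutoff: float = 0.06,
                    cosine_tolerance: float = 0.01) -> ExposureVector:
    """Non-negative least-squares refit with greedy minor-signature pruning.

    Solves ``min ||m - P e||_2, e >= 0`` for the normalised spectrum ``m``,
    then repeatedly zeroes the smallest exposure below ``prune_cutoff`` and
    refits, accepting each removal only while the reconstruction cosine
    similarity stays within ``cosine_tolerance`` of the unpruned fit.
    Returned proportions sum to 1 with pruned entries exactly 0.
    """
    if spectrum.space != catalog.space:
        raise ValueError(f"space mismatch: {spectrum.space} vs {catalog.space}")
    total = spectrum.total
    if total <= 0:
        raise ValueError("cannot refit a zero spectrum")
    m = spectrum.counts / total
    P = catalog.profiles.to_numpy(dtype=float)
    names = catalog.names

    def fit(active: list[int]):
        e_sub, _ = nnls(P[:, active], m)
        e = np.zeros(len(names))
        e[active] = e_sub
        return e, _cosine(P @ e, m)

    active = list(range(len(names)))
    e, cos_full = fit(active)
    cos = cos_full
    while True:
        s = e.sum()
        props = e / s if s > 0 else e
        minor = [i for i in active if 0 <= props[i] < prune_cutoff]
        if not minor or len(active) == 1:
            break
        drop = min(minor, key=lambda i: (props[i], names[i]))
        trial_active = [i for i in active if i != drop]
        e_trial, cos_trial = fit(trial_active)
        if cos_full - cos_trial < cosine_tolerance:
            active, e, cos = trial_active, e_trial, cos_trial
        else:
            break
    s = e.sum()
    props = e / s if s > 0 else e
    return ExposureVector(
        proportions=pd.Series(props, index=names),
        cosine=cos, n_mutations=total)


def per_tier_signatures(mutations: pd.DataFrame, tiers: pd.Series,
                        catalog: SignatureCatalog, case: str = "",
                        by: str = "tier-pooled", min_mutations: int = 20,
                        **refit_kw) -> pd.DataFrame:
    """Refit signature exposures per temporal tier for one case.

    ``tiers`` maps mutation_id -> {early, intermediate, late}. With
    ``by='tier-per-tumor'`` the late tier is refit separately per tumor
    (late mutations are private, so each tumor contributes its own spectrum);
    ``'tier-pooled'`` pools them. Tiers with fewer than ``min_mutations``
    distinct mutations are refit anyway but flagged low-confidence.
    Returns a table with one row per (case, tier[, tumor]) and one column per
    catalog signature, plus ``n_mutations``, ``cosine``, ``low_confidence``.
    """
    if by not in ("tier-pooled", "tier-per-tumor"):
        raise ValueError(f"unknown mode {by!r}")
    muts = mutations.drop_duplicates(subset="mutation_id").copy()
    muts["tier"] = muts["mutation_id"].map(tiers)
    rows = []

    def one(sub: pd.DataFrame, tier: str, tumor: str = ""):
        if sub.empty:
            return
        spec = build_sbs96_spectrum(sub, source=f"{case}:{tier}")
        if spec.total == 0:
            return
        exp = refit_exposures(spec, catalog, **refit_kw)
        rec = {"case": case, "tier": tier, "tumor": tumor,
               "n_mutations": int(spec.total), "cosine": exp.cosine,
               "low_confidence": spec.total < min_mutations}
        rec.update(exp.proportions.to_dict())
        rows.append(rec)

    for tier in ("early", "intermediate", "late"):
        sub = muts[muts["tier"] == tier]
        if sub.empty:
            continue
        if tier == "late" and by == "tier-per-tumor":
            # late mutations are private: use the emitting tumor's rows
            per_tumor = mutations[mutations["mutation_id"].isin(sub["mutation_id"])]
            for tumor, tsub in per_tumor.groupby("sample"):
                one(tsub.drop_duplicates(subset="mutation_id"), tier, tumor)
        else:
            one(sub, tier)
    return pd.DataFrame(rows)
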