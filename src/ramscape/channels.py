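"""Mutation-channel spaces: SBS96, ID83 and RS32.

Channel orders are fixed here and used everywhere a spectrum or catalog is
built, so count vectors and reference profiles always align.

* SBS96 — single-base substitutions on the pyrimidine strand, one channel per
  (5' base, ref>alt, 3' base): ordered by substitution class
  (C>A, C>G, C>T, T>A, T>C, T>G), then 5' base, then 3' base, each A<C<G<T.
  Channel labels look like ``A[C>T]G``.
* ID83 — small insertions/deletions binned by type, length and sequence
  context (homopolymer length for 1-bp events, repeat-unit count or
  microhomology length for longer ones).
* RS32 — rearrangements: {clustered, non-clustered} x {del, dup, inv} x five
  size bins plus a size-free translocation channel per cluster state.
"""

from __future__ import annotations

import itertools

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = ["A", "C", "G", "T"]

SBS96_CHANNELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
SBS96_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def sbs96_channel(ref: str, alt: str, context: str) -> str:
    """Map a substitution with its trinucleotide context to an SBS96 label.

    ``context`` is the reference trinucleotide centred on the mutated base.
    Purine-reference records are reverse-complemented onto the pyrimidine
    strand first. Raises ``KeyError`` on ambiguous bases (N etc.).
    """
    ref, alt = ref.upper(), alt.upper()
    context = context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if any(b not in COMPLEMENT for b in context) or alt not in COMPLEMENT:
        raise ValueError(f"ambiguous base in {context!r}>{alt!r}")
    if ref in ("G", "A"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context = revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


# --- ID83 -------------------------------------------------------------------

def _id83_channels() -> list[str]:
    ch = []
    # 1-bp deletions / insertions in homopolymers, by deleted/inserted base.
    for base in ("C", "T"):
        for hp in ("1", "2", "3", "4", "5", "6+"):
            ch.append(f"DEL.{base}.1.{hp}")
    for base in ("C", "T"):
        for hp in ("0", "1", "2", "3", "4", "5+"):
            ch.append(f"INS.{base}.1.{hp}")
    # >=2 bp deletions / insertions at repeats, by repeat-unit count.
    for ln in ("2", "3", "4", "5+"):
        for rep in ("1", "2", "3", "4", "5", "6+"):
            ch.append(f"DEL.repeats.{ln}.{rep}")
    for ln in ("2", "3", "4", "5+"):
        for rep in ("0", "1", "2", "3", "4", "5+"):
            ch.append(f"INS.repeats.{ln}.{rep}")
    # Deletions with flanking microhomology.
    for ln, mhs in (("2", ["1"]), ("3", ["1", "2"]), ("4", ["1", "2", "3"]),
                    ("5+", ["1", "2", "3", "4", "5+"])):
        for mh in mhs:
            ch.append(f"DEL.MH.{ln}.{mh}")
    assert len(ch) == 83
    return ch


ID83_CHANNELS = _id83_channels()
ID83_INDEX = {c: i for i, c in enumerate(ID83_CHANNELS)}


def _cap(value: int, top: int) -> str:
    return f"{top}+" if value >= top else str(value)


def id83_channel(indel_type: str, length: int, base: str | None = None,
                 homopolymer_len: int = 0, repeat_count: int = 0,
                 mh_len: int = 0) -> str:
    """Map an indel with its sequence-context summary to an ID83 label.

    ``indel_type`` is ``ins`` or ``del``; for 1-bp events ``base`` is the
    pyrimidine-strand inserted/deleted base and ``homopolymer_len`` the run
    length of that base adjacent to the event (for deletions, including the
    deleted base). For longer deletions, microhomology takes precedence over
    repeat context when ``mh_len`` > 0 and ``repeat_count`` <= 1.
    """
    indel_type = indel_type.lower()
    if indel_type not in ("ins", "del"):
        raise ValueError(f"unknown indel type {indel_type!r}")
    if length < 1:
        raise ValueError("indel length must be >= 1")
    if length == 1:
        b = (base or "").upper()
        if b in ("G", "A"):
            b = COMPLEMENT[b]
        if b not in ("C", "T"):
            raise ValueError(f"1-bp indel needs base C/T/G/A, got {base!r}")
        if indel_type == "del":
            hp = _cap(max(homopolymer_len, 1), 6)
            return f"DEL.{b}.1.{hp}"
        hp = _cap(homopolymer_len, 5)
        return f"INS.{b}.1.{hp}"
    ln = _cap(length, 5)
    if indel_type == "del" and mh_len > 0 and repeat_count <= 1:
        mh = _cap(min(mh_len, length - 1), 5)
        return f"DEL.MH.{ln}.{mh}"
    if indel_type == "del":
        rep = _cap(max(repeat_count, 1), 6)
        return f"DEL.repeats.{ln}.{rep}"
    rep = _cap(repeat_count, 5)
    return f"INS.repeats.{ln}.{rep}"


# --- RS32 -------------------------------------------------------------------

SV_SIZE_BINS = ["1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb"]
_SV_SIZE_EDGES = [1e4, 1e5, 1e6, 1e7]
SV_TYPES = ["del", "dup", "inv"]


def _rs32_channels() -> list[str]:
    ch = []
    for clus in ("clustered", "non-clustered"):
        for typ, size in itertools.product(SV_TYPES, SV_SIZE_BINS):
            ch.append(f"{clus}:{typ}:{size}")
        ch.append(f"{clus}:tra")
    assert len(ch) == 32
    return ch


RS32_CHANNELS = _rs32_channels()
RS32_INDEX = {c: i for i, c in enumerate(RS32_CHANNELS)}


def sv_size_bin(size: float) -> str:
    for edge, label in zip(_SV_SIZE_EDGES, SV_SIZE_BINS):
        if size <= edge:
            return label
    return SV_SIZE_BINS[-1]


def rs32_channel(svtype: str, clustered: bool, size: float | None = None) -> str:
    """Map one rearrangement to its RS32 channel label."""
    clus = "clustered" if clustered else "non-clustered"
    svtype = svtype.lower()
    aliases = {"deletion": "del", "duplication": "dup", "inversion": "inv",
               "translocation": "tra"}
    svtype = aliases.get(svtype, svtype)
    if svtype == "tra":
        return f"{clus}:tra"
    if svtype not in SV_TYPES:
        raise ValueError(f"unknown svtype {svtype!r}")
    if size is None or size <= 0:
        raise ValueError("intra-chromosomal SV needs a positive size")
    return f"{clus}:{svtype}:{sv_size_bin(size)}"


CHANNEL_SPACES = {
    "SBS96": SBS96_CHANNELS,
    "ID83": ID83_CHANNELS,
    "RS32": RS32_CHANNELS,
}
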