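"""CRISPR target-site scanning and cloning-oligo design for Cas9 and Cas12a.

Cas9 (SpCas9) recognises a 20-nt protospacer followed by an NGG PAM on its
3' side and cuts bluntly 3 bp inside the protospacer, PAM-proximal.
Cas12a (LbCas12a) recognises a TTTV PAM on the 5' side of the protospacer
(23 nt by default here) and makes a staggered, PAM-distal cut.

Oligo pairs for level-1 GoldenGate cloning are the annealed protospacer
duplex flanked by architecture-specific 4-nt overhangs that match the
BsaI-generated ends of the corresponding guide accepter:

===========  ===========  ===========
architecture fwd overhang rev overhang
===========  ===========  ===========
CAS9_A_TaU6  CTTG         AAAC
CAS9_A_TaU3  AGCA         AAAC
CAS9_A_HvU3  AGCA         AAAC
CAS12A_V2    AGAT         GGCC
CAS12A_V3    AGAT         ATTA
===========  ===========  ===========
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Nuclease",
    "NucleaseSpec",
    "TargetSite",
    "GuideArchitecture",
    "ARCHITECTURES",
    "OligoPair",
    "CAS9",
    "CAS12A",
    "scan_targets",
    "scan_fasta",
    "design_oligo_pair",
    "design_batch",
    "reverse_complement",
    "sites_to_table",
    "oligos_to_table",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string (uppercased)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


class Nuclease(str, Enum):
    CAS9 = "Cas9"
    CAS12A = "Cas12a"


class PamSide(str, Enum):
    THREE_PRIME = "three_prime"
    FIVE_PRIME = "five_prime"


@dataclass(frozen=True)
class NucleaseSpec:
    """PAM pattern, geometry and protospacer length for one nuclease.

    ``cut_offsets`` are (top, bottom) strand cut positions relative to the
    PAM-proximal end of the protospacer, used only to centre the default
    cut window of the amplicon caller.  Cas9 cuts bluntly 3 bp 5' of the
    PAM; Cas12a cuts staggered after protospacer positions 18/23.
    """

    name: Nuclease
    pam_pattern: str
    pam_side: PamSide
    protospacer_length: int
    cut_offsets: tuple[int, int]

    def __post_init__(self) -> None:
        if not set(self.pam_pattern.upper()) <= set(IUPAC):
            raise ValueError(f"pam_pattern {self.pam_pattern!r} is not IUPAC")
        if self.protospacer_length < 15:
            raise ValueError("protospacer_length must be >= 15")
        if self.name is Nuclease.CAS9 and self.pam_side is not PamSide.THREE_PRIME:
            raise ValueError("Cas9 PAM is 3' of the protospacer")
        if self.name is Nuclease.CAS12A and self.pam_side is not PamSide.FIVE_PRIME:
            raise ValueError("Cas12a PAM is 5' of the protospacer")


CAS9 = NucleaseSpec(Nuclease.CAS9, "NGG", PamSide.THREE_PRIME, 20, (-3, -3))
CAS12A = NucleaseSpec(Nuclease.CAS12A, "TTTV", PamSide.FIVE_PRIME, 23, (18, 23))


def nuclease_spec(name: str, protospacer_length: int | None = None) -> NucleaseSpec:
    """Look up a default spec by name, optionally overriding the length."""
    base = {"cas9": CAS9, "cas12a": CAS12A}[name.strip().lower()]
    if protospacer_length is None or protospacer_length == base.protospacer_length:
        return base
    return NucleaseSpec(base.name, base.pam_pattern, base.pam_side,
                        protospacer_length, base.cut_offsets)


@dataclass(frozen=True)
class TargetSite:
    """A protospacer+PAM hit.

    ``start`` is the 0-based offset of the leftmost protospacer base on the
    forward strand regardless of ``strand``; ``protospacer`` and ``pam`` are
    reported in the site's own (strand) reading orientation, so for a minus
    strand site ``reverse_complement(protospacer)`` equals the forward-strand
    slice ``[start, start+len)``.
    """

    seq_id: str
    start: int
    strand: str
    protospacer: str
    pam: str


@dataclass(frozen=True)
class GuideArchitecture:
    """A level-1 oligo template: name plus the two cloning overhangs."""

    name: str
    nuclease: Nuclease
    fwd_overhang: str
    rev_overhang: str


ARCHITECTURES: dict[str, GuideArchitecture] = {
    a.name: a
    for a in (
        GuideArchitecture("CAS9_A_TaU6", Nuclease.CAS9, "CTTG", "AAAC"),
        GuideArchitecture("CAS9_A_TaU3", Nuclease.CAS9, "AGCA", "AAAC"),
        GuideArchitecture("CAS9_A_HvU3", Nuclease.CAS9, "AGCA", "AAAC"),
        GuideArchitecture("CAS12A_V2", Nuclease.CAS12A, "AGAT", "GGCC"),
        GuideArchitecture("CAS12A_V3", Nuclease.CAS12A, "AGAT", "ATTA"),
    )
}


@dataclass(frozen=True)
class OligoPair:
    """Forward/reverse cloning oligos for one protospacer.

    forward = fwd_overhang + protospacer
    reverse = rev_overhang + reverse_complement(protospacer)
    """

    forward: str
    reverse: str
    architecture: GuideArchitecture
    protospacer: str


def _iupac_match(pattern: str, text: str) -> bool:
    return len(pattern) == len(text) and all(
        t in IUPAC[p] for p, t in zip(pattern, text)
    )


def scan_targets(sequence: str, spec: NucleaseSpec, seq_id: str = "seq") -> list[TargetSite]:
    """Find every Cas9/Cas12a target site on both strands of ``sequence``.

    A site is a full-length protospacer window with the PAM immediately
    adjacent on the side the nuclease requires.  N bases in the sequence
    never match, neither inside the protospacer nor in the PAM.  Windows
    running past either sequence end are silently skipped.  Sites are
    sorted by (start, strand); see :class:`TargetSite` for the minus-strand
    coordinate convention.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")

    L = spec.protospacer_length
    P = len(spec.pam_pattern)
    n = len(seq)
    sites: list[TargetSite] = []

    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for i in range(0, n - L + 1):
            proto = s[i:i + L]
            if "N" in proto:
                continue
            if spec.pam_side is PamSide.THREE_PRIME:
                pam = s[i + L:i + L + P]
            else:
                pam = s[i - P:i] if i >= P else ""
            if len(pam) != P or "N" in pam:
                continue
            if not _iupac_match(spec.pam_pattern, pam):
                continue
            start = i if strand == "+" else n - i - L
            sites.append(TargetSite(seq_id, start, strand, proto, pam))

    sites.sort(key=lambda t: (t.start, t.strand))
    return sites


def scan_fasta(path, spec: NucleaseSpec) -> list[TargetSite]:
    """Scan every record of a (multi-)FASTA file."""
    out: list[TargetSite] = []
    for rec in SeqIO.parse(path, "fasta"):
        out.extend(scan_targets(str(rec.seq), spec, seq_id=rec.id))
    return out


def design_oligo_pair(
    protospacer: str,
    architecture: GuideArchitecture | str,
    *,
    length_override: int | None = None,
) -> OligoPair:
    """Build the level-1 cloning oligo pair for one protospacer.

    The protospacer excludes the PAM.  Length must match the nuclease
    default (20 for Cas9 architectures, 23 for Cas12a) unless
    ``length_override`` is given.  A Cas12a protospacer beginning with TTT
    looks like it still carries its PAM and triggers a warning.
    """
    if isinstance(architecture, str):
        try:
            architecture = ARCHITECTURES[architecture]
        except KeyError:
            raise ValueError(
                f"unknown architecture {architecture!r}; "
                f"choose from {sorted(ARCHITECTURES)}"
            ) from None
    proto = protospacer.upper()
    if not set(proto) <= set("ACGT"):
        bad = sorted(set(proto) - set("ACGT"))
        raise ValueError(f"protospacer contains non-ACGT characters: {bad}")
    expected = length_override
    if expected is None:
        expected = 20 if architecture.nuclease is Nuclease.CAS9 else 23
    if len(proto) != expected:
        raise ValueError(
            f"protospacer length {len(proto)} != expected {expected} "
            f"for {architecture.name}"
        )
    if architecture.nuclease is Nuclease.CAS12A and proto.startswith("TTT"):
        warnings.warn(
            "Cas12a protospacer begins with TTT: check the TTTV PAM was "
            "not accidentally included (the protospacer excludes the PAM)",
            stacklevel=2,
        )
    return OligoPair(
        forward=architecture.fwd_overhang + proto,
        reverse=architecture.rev_overhang + reverse_complement(proto),
        architecture=architecture,
        protospacer=proto,
    )


def design_batch(rows: Iterable[tuple[str, str, str]]) -> list[tuple[str, OligoPair]]:
    """Design oligos for (name, protospacer, architecture) rows."""
    return [(name, design_oligo_pair(proto, arch)) for name, proto, arch in rows]


def sites_to_table(sites: Iterable[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.seq_id, t.start, t.strand, t.protospacer, t.pam) for t in sites],
        columns=["seq_id", "start", "strand", "protospacer", "pam"],
    )


def oligos_to_table(named: Iterable[tuple[str, OligoPair]]) -> pd.DataFrame:
    return pd.DataFrame(
        [(n, p.architecture.name, p.forward, p.reverse) for n, p in named],
        columns=["name", "architecture", "forward", "reverse"],
    )


def plate_layout(named: list[tuple[str, OligoPair]]) -> pd.DataFrame:
    """96-well ordering layout: forward/reverse oligos in paired wells."""
    rows = "ABCDEFGH"
    wells = [f"{r}{c}" for c in range(1, 13) for r in rows]
    recs = []
    i = 0
    for name, pair in named:
        for suffix, seq in (("_F", pair.forward), ("_R", pair.reverse)):
            if i >= len(wells):
                raise ValueError("more than 96 oligos; split across plates")
            recs.append((wells[i], name + suffix, seq))
            i += 1
    return pd.DataFrame(recs, columns=["well", "oligo", "sequence"])
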