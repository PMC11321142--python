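"""Amplicon deep-sequencing mutation calling and Sanger classification.

Re-implements the analysis used to score CRISPR editing outcomes from
paired-end amplicon reads mapped to target loci (SAM input; mapping, e.g.
bwa mem, is upstream):

1. per-locus amplicon boundaries are inferred as the modal start points of
   the read pairs (``modal_starts``);
2. read pairs are usable only when both mates start exactly at those
   boundaries (``filter_usable``);
3. indel patterns are extracted by walking the CIGAR strings and keeping
   insertion/deletion operations that touch the cut window
   (``extract_pattern``);
4. the per-sample, per-locus report gives the percentage of usable pairs
   supporting a wild-type allele and the full pattern spectrum
   (``call_locus``).

Substitutions never count as mutations: NHEJ outcomes of interest are
indels, and treating mismatches as edits would make the caller sensitive
to sequencing error.  Insertions are counted as mutant by default (Cas9
NHEJ commonly produces +1 insertions); ``deletions_only=True`` restores
strictly deletion-based calling.

Coordinates are 0-based half-open internally (SAM's 1-based starts are
converted on input); pattern keys print 1-based positions.

A Sanger-style classifier (``sanger_classify``) aligns a base-called
query to the reference with an affine-gap global alignment and flags
mutation when any alignment gap intersects the cut window.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
import pysam
from Bio import Align

__all__ = [
    "LocusSpec",
    "AlignedReadPair",
    "IndelPattern",
    "WT_PATTERN",
    "LocusCallReport",
    "load_alignments",
    "load_sam_text",
    "modal_starts",
    "filter_usable",
    "extract_pattern",
    "call_locus",
    "sanger_classify",
    "reports_to_table",
    "spectrum_to_table",
    "DEFAULT_CUT_WINDOW_HALF",
]

#: default half-width of the cut window (cut site +/- 15 nt)
DEFAULT_CUT_WINDOW_HALF = 15

_CIGAR_OPS = set("MIDNSHP=X")
_CONSUMES_REF = set("MDN=X")
_CONSUMES_QUERY = set("MIS=X")


@dataclass(frozen=True)
class LocusSpec:
    """One target locus: reference sequence plus the cut window, a 0-based
    half-open interval around the expected nuclease cut site."""

    locus_id: str
    reference: str
    cut_window: tuple[int, int]
    expected_starts: tuple[int, int] | str | None = "auto"

    def __post_init__(self) -> None:
        a, b = self.cut_window
        if not (0 <= a < b <= len(self.reference)):
            raise ValueError(
                f"{self.locus_id}: cut_window {self.cut_window} outside "
                f"reference bounds [0, {len(self.reference)})"
            )

    @classmethod
    def around_cut_site(cls, locus_id: str, reference: str, cut_site: int,
                        half: int = DEFAULT_CUT_WINDOW_HALF) -> "LocusSpec":
        a = max(0, cut_site - half)
        b = min(len(reference), cut_site + half)
        return cls(locus_id, reference, (a, b))


def load_loci_fasta_tsv(fasta_path, tsv_path) -> list["LocusSpec"]:
    """Build loci from a reference FASTA plus a TSV with columns
    locus_id, window_start, window_end (0-based half-open)."""
    from Bio import SeqIO

    refs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}
    table = pd.read_csv(tsv_path, sep="\t")
    loci = []
    for row in table.itertuples():
        if row.locus_id not in refs:
            raise ValueError(f"locus {row.locus_id!r} not in {fasta_path}")
        loci.append(LocusSpec(row.locus_id, refs[row.locus_id],
                              (int(row.window_start), int(row.window_end))))
    return loci


@dataclass(frozen=True)
class AlignedReadPair:
    pair_id: str
    locus_id: str
    start1: int
    start2: int
    cigar1: str
    cigar2: str
    proper_pair: bool = True


@dataclass(frozen=True)
class IndelPattern:
    """Ordered insertion/deletion events on reference coordinates.

    ``events`` is a tuple of (op, ref_pos, length) with op in {"I", "D"}
    and 0-based ref_pos; the canonical ``key`` prints 1-based positions and
    round-trips via :meth:`from_key`.  An empty event list is wild type.
    """

    events: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "events",
                           tuple(sorted(self.events, key=lambda e: (e[1], e[0]))))
        for op, pos, length in self.events:
            if op not in ("I", "D") or length <= 0 or pos < 0:
                raise ValueError(f"bad indel event {(op, pos, length)}")

    @property
    def is_wildtype(self) -> bool:
        return not self.events

    @property
    def key(self) -> str:
        return ";".join(f"{op}:{pos + 1}:{length}" for op, pos, length in self.events)

    @classmethod
    def from_key(cls, key: str) -> "IndelPattern":
        if not key:
            return cls()
        events = []
        for chunk in key.split(";"):
            op, pos, length = chunk.split(":")
            events.append((op, int(pos) - 1, int(length)))
        return cls(tuple(events))

    @classmethod
    def deletion(cls, ref_pos: int, length: int) -> "IndelPattern":
        return cls((("D", ref_pos, length),))

    @classmethod
    def insertion(cls, ref_pos: int, length: int) -> "IndelPattern":
        return cls((("I", ref_pos, length),))


WT_PATTERN = IndelPattern()


@dataclass
class LocusCallReport:
    sample_id: str
    locus_id: str
    total_pairs: int
    usable_pairs: int
    wt_pairs: int
    pct_wt: float                       # NaN when no usable pairs
    pct_mutant: float
    pattern_counts: dict = field(default_factory=dict)
    boundaries: tuple[int, int] | None = None
    discordant_pairs: int = 0
    no_usable: bool = False

    def __post_init__(self) -> None:
        assert self.usable_pairs <= self.total_pairs
        assert self.wt_pairs <= self.usable_pairs
        assert sum(self.pattern_counts.values()) + self.wt_pairs == self.usable_pairs


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    if not cigar or cigar == "*":
        raise ValueError(f"malformed CIGAR {cigar!r}")
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS:
            if not num:
                raise ValueError(f"malformed CIGAR {cigar!r}")
            length = int(num)
            if length <= 0:
                raise ValueError(f"non-positive CIGAR length in {cigar!r}")
            out.append((ch, length))
            num = ""
        else:
            raise ValueError(f"malformed CIGAR {cigar!r}")
    if num:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return out


def _ref_span(start: int, cigar: str) -> tuple[int, int]:
    end = start
    for op, length in _parse_cigar(cigar):
        if op in _CONSUMES_REF:
            end += length
    return start, end


def load_alignments(source, loci) -> tuple[dict, Counter]:
    """Read a SAM file and group primary, mapped read pairs by locus.

    ``source`` is a path to a SAM file.  Returns
    ``(pairs_by_locus, counters)`` where counters track dropped records
    (orphan mates, unknown references, non-primary/unmapped records).
    """
    by_id = {l.locus_id: l for l in loci}
    counters: Counter = Counter()
    mates: dict[tuple[str, str], list] = {}
    with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                counters["non_primary_or_unmapped"] += 1
                continue
            if rec.reference_name not in by_id:
                counters["unknown_reference"] += 1
                continue
            mates.setdefault((rec.query_name, rec.reference_name), []).append(rec)
    pairs: dict[str, list[AlignedReadPair]] = {l.locus_id: [] for l in loci}
    for (qname, ref), recs in mates.items():
        if len(recs) != 2:
            counters["orphan_pairs"] += 1
            continue
        r1, r2 = recs
        pairs[ref].append(AlignedReadPair(
            pair_id=qname,
            locus_id=ref,
            start1=r1.reference_start,
            start2=r2.reference_start,
            cigar1=r1.cigarstring,
            cigar2=r2.cigarstring,
            proper_pair=bool(r1.is_proper_pair and r2.is_proper_pair),
        ))
    for locus_id in pairs:
        pairs[locus_id].sort(key=lambda p: p.pair_id)
    return pairs, counters


def load_sam_text(text: str, loci, tmp_path=None):
    """Convenience wrapper: parse SAM given as a string (via a temp file)."""
    import tempfile, os

    if tmp_path is not None:
        path = str(tmp_path)
        with open(path, "w") as fh:
            fh.write(text)
        return load_alignments(path, loci)
    with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        return load_alignments(path, loci)
    finally:
        os.unlink(path)


def modal_starts(pairs) -> tuple[int, int]:
    """Amplicon boundaries: the modal lower and upper mate start positions,
    ties broken toward the smaller coordinate."""
    if not pairs:
        raise ValueError("no pairs to infer boundaries from")
    lows = Counter(min(p.start1, p.start2) for p in pairs)
    highs = Counter(max(p.start1, p.start2) for p in pairs)

    def _mode(counter: Counter) -> int:
        best = max(counter.values())
        return min(pos for pos, c in counter.items() if c == best)

    return _mode(lows), _mode(highs)


def filter_usable(pairs, boundaries: tuple[int, int]):
    """Keep pairs whose two mate starts equal the boundaries exactly
    (orientation-agnostic).  A deletion upstream of a mate's start shifts
    the start and excludes the pair — an inherent property of this filter."""
    b = tuple(sorted(boundaries))
    return [p for p in pairs if tuple(sorted((p.start1, p.start2))) == b]


def _mate_events(start: int, cigar: str, window: tuple[int, int]):
    w0, w1 = window
    events = []
    ref = start
    for op, length in _parse_cigar(cigar):
        if op == "D":
            if ref < w1 and ref + length > w0:      # deletion touches window
                events.append(("D", ref, length))
            ref += length
        elif op == "I":
            if w0 <= ref < w1:                      # insertion point inside
                events.append(("I", ref, length))
        elif op in _CONSUMES_REF:
            ref += length
    return events


def extract_pattern(pair: AlignedReadPair, locus: LocusSpec,
                    deletions_only: bool = False):
    """Indel pattern of a usable pair within the locus cut window.

    The pattern comes from the mate overlapping the cut window; if both
    overlap and disagree the pair is flagged discordant and the union of
    events is returned.  Returns ``(pattern, discordant)``.
    """
    window = locus.cut_window
    per_mate = []
    for start, cigar in ((pair.start1, pair.cigar1), (pair.start2, pair.cigar2)):
        try:
            s, e = _ref_span(start, cigar)
        except ValueError as err:
            raise ValueError(f"pair {pair.pair_id}: {err}") from None
        if s < window[1] and e > window[0]:
            ev = _mate_events(start, cigar, window)
            if deletions_only:
                ev = [x for x in ev if x[0] == "D"]
            per_mate.append(tuple(sorted(ev)))
    if not per_mate:
        return WT_PATTERN, False
    if len(per_mate) == 1 or per_mate[0] == per_mate[1]:
        return IndelPattern(per_mate[0]), False
    union = tuple(sorted(set(per_mate[0]) | set(per_mate[1])))
    return IndelPattern(union), True


def call_locus(sample_id: str, pairs, locus: LocusSpec,
               deletions_only: bool = False) -> LocusCallReport:
    """Full per-locus calling: boundaries -> usable filter -> patterns.

    With zero usable pairs the percentage fields are NaN and the report is
    flagged, never an exception.
    """
    total = len(pairs)
    if total == 0:
        return LocusCallReport(sample_id, locus.locus_id, 0, 0, 0,
                               float("nan"), float("nan"), {}, None, 0, True)
    if locus.expected_starts not in (None, "auto"):
        boundaries = tuple(locus.expected_starts)
    else:
        boundaries = modal_starts(pairs)
    usable = filter_usable(pairs, boundaries)
    counts: Counter = Counter()
    wt = 0
    discordant = 0
    for p in usable:
        pattern, disc = extract_pattern(p, locus, deletions_only=deletions_only)
        discordant += disc
        if pattern.is_wildtype:
            wt += 1
        else:
            counts[pattern.key] += 1
    n_usable = len(usable)
    if n_usable:
        pct_wt = 100.0 * wt / n_usable
        return LocusCallReport(sample_id, locus.locus_id, total, n_usable, wt,
                               pct_wt, 100.0 - pct_wt, dict(counts),
                               boundaries, discordant, False)
    return LocusCallReport(sample_id, locus.locus_id, total, 0, 0,
                           float("nan"), float("nan"), {}, boundaries, 0, True)


def sanger_classify(query: str, locus: LocusSpec,
                    match: float = 2.0, mismatch: float = -1.0,
                    gap_open: float = -6.0, gap_extend: float = -1.0):
    """Classify a base-called Sanger read against the locus reference.

    Global pairwise alignment with affine gap penalties; the read is
    mutated iff any alignment gap (insertion or deletion) intersects the
    cut window.  Substitutions alone never flag mutation.  Returns
    ``(mutated, IndelPattern)`` with the pattern restricted to the window.
    """
    query = query.upper().replace("\n", "")
    if len(query) < 50:
        raise ValueError("query too short to classify (need >= 50 nt)")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(locus.reference, query)[0]
    ref_blocks, q_blocks = aln.aligned
    w0, w1 = locus.cut_window
    events = []
    for i in range(1, len(ref_blocks)):
        ref_gap = int(ref_blocks[i][0] - ref_blocks[i - 1][1])
        q_gap = int(q_blocks[i][0] - q_blocks[i - 1][1])
        pos = int(ref_blocks[i - 1][1])
        if ref_gap > 0 and (pos < w1 and pos + ref_gap > w0):
            events.append(("D", pos, ref_gap))
        if q_gap > 0 and w0 <= pos < w1:
            events.append(("I", pos, q_gap))
    pattern = IndelPattern(tuple(events))
    return (not pattern.is_wildtype), pattern


def reports_to_table(reports) -> pd.DataFrame:
    """Per-sample report TSV layout (1-based-friendly, raw percentages)."""
    return pd.DataFrame(
        [
            (r.sample_id, r.locus_id, r.total_pairs, r.usable_pairs,
             r.wt_pairs, r.pct_wt, r.pct_mutant)
            for r in reports
        ],
        columns=["sample", "locus", "total", "usable", "wt",
                 "pct_wt", "pct_mutant"],
    )


def spectrum_to_table(reports) -> pd.DataFrame:
    rows = []
    for r in reports:
        for key, count in sorted(r.pattern_counts.items()):
            rows.append((r.sample_id, r.locus_id, key, count))
    return pd.DataFrame(rows, columns=["sample", "locus", "pattern", "count"])
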