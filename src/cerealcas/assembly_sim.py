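"""In-silico GoldenGate: type-IIS digestion, overhang ligation, plan checking.

Models one-pot digestion-ligation with BsaI and BpiI.  Both enzymes cut
outside their recognition sequence leaving programmable 4-nt 5' overhangs,
which is what makes scarless, ordered multi-fragment assembly possible:
once a fragment has ligated into the product the recognition sites are
gone and the join cannot be re-cut.

Double-stranded fragments are represented by their top-strand sequence
spanning both cut regions; a 4-nt overhang is stored as the top-strand
sequence of the single-stranded region, so two ends are compatible exactly
when their overhang strings are equal.  The simulator answers "is this
design correct" — methylation sensitivity, partial digestion and ligation
kinetics are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .guide_design import reverse_complement

__all__ = [
    "TypeIISEnzyme",
    "BSAI",
    "BPII",
    "ENZYMES",
    "PartRecord",
    "Fragment",
    "AssemblyResult",
    "digest",
    "ligate",
    "simulate_reaction",
    "simulate_plan",
    "part_to_seqrecord",
    "seqrecord_to_part",
]

#: annotation labels marking fragments discarded during backbone/insert selection
DROPOUT_LABELS = frozenset({"dropout", "lacz", "rfp"})
BACKBONE_LABELS = frozenset({"backbone"})


@dataclass(frozen=True)
class TypeIISEnzyme:
    """A type-IIS enzyme cutting ``spacer`` nt downstream of its site,
    leaving a 4-nt 5' overhang."""

    name: str
    recognition: str
    spacer: int
    overhang_length: int = 4


BSAI = TypeIISEnzyme("BsaI", "GGTCTC", 1)
BPII = TypeIISEnzyme("BpiI", "GAAGAC", 2)
ENZYMES = {"BsaI": BSAI, "BpiI": BPII}


@dataclass
class PartRecord:
    """A cloning part: accepter plasmid, insert module or end linker.

    ``annotations`` are (label, start, end, strand) features on the part's
    own coordinates; labels in :data:`DROPOUT_LABELS` / "backbone" drive
    fragment selection during :func:`simulate_reaction`.
    """

    id: str
    sequence: str
    circular: bool
    role: str = "insert"                   # accepter | insert | end_linker
    annotations: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not set(self.sequence) <= set("ACGT"):
            raise ValueError(f"part {self.id}: sequence must be ACGT")


@dataclass
class Fragment:
    """A digestion product.  ``sequence`` is the top strand spanning both
    4-nt cut regions; empty overhang means a blunt (uncut) end."""

    sequence: str
    five_overhang: str
    three_overhang: str
    origin_part: str
    annotations: list[tuple] = field(default_factory=list)

    @property
    def core_length(self) -> int:
        """Length counted once per nucleotide (right overhang region is
        shared with the next fragment)."""
        return len(self.sequence) - len(self.three_overhang)


@dataclass
class AssemblyResult:
    product: str | None                    # circular top-strand sequence
    joins: list[tuple]                     # (origin_part, via overhang)
    diagnostics: list[str]
    annotations: list[tuple] = field(default_factory=list)


class GeometryError(ValueError):
    """Cut sites overlap, producing negative-length fragments."""


def _find_cuts(seq: str, circular: bool, enzymes) -> list[tuple[int, str]]:
    """Top-strand cut positions (start of the 4-nt cut region) for all
    recognition sites on both strands."""
    n = len(seq)
    search = seq + seq if circular else seq
    cuts: set[int] = set()
    for enz in enzymes:
        rec = enz.recognition
        rc = reverse_complement(rec)
        k = len(rec)
        for p in range(len(search) - k + 1):
            if circular and p >= n:
                break
            window = search[p:p + k]
            if window == rec:
                t = p + k + enz.spacer
                if circular:
                    cuts.add(t % n)
                elif t + enz.overhang_length <= n:
                    cuts.add(t)
                # else: cut runs off the end of a linear part; site inert
            if window == rc:
                t = p - enz.spacer - enz.overhang_length
                if circular:
                    cuts.add(t % n)
                elif t >= 0:
                    cuts.add(t)
    return sorted(cuts)


def _shift_annotations(annotations, a: int, b: int, n: int, circular: bool):
    """Annotations fully contained in span [a, b) (doubled coords for
    circular parts), re-based to the fragment."""
    out = []
    for (label, s, e, strand) in annotations:
        candidates = [(s, e), (s + n, e + n)] if circular else [(s, e)]
        for cs, ce in candidates:
            if a <= cs and ce <= b:
                out.append((label, cs - a, ce - a, strand))
                break
    return out


def digest(part: PartRecord, enzymes) -> list[Fragment]:
    """Cut a part with a set of type-IIS enzymes.

    Returns the list of double-stranded fragments; a part with no
    recognition sites comes back intact as a single blunt/uncut fragment.
    """
    if not enzymes:
        raise ValueError("enzyme set must be non-empty")
    enzymes = [ENZYMES[e] if isinstance(e, str) else e for e in enzymes]
    seq = part.sequence
    n = len(seq)
    cuts = _find_cuts(seq, part.circular, enzymes)
    if not cuts:
        return [Fragment(seq, "", "", part.id, list(part.annotations))]

    ov = enzymes[0].overhang_length  # both toolkit enzymes leave 4-nt ends
    for a, b in zip(cuts, cuts[1:]):
        if b - a < ov:
            raise GeometryError(
                f"part {part.id}: overlapping cut sites at {a}/{b}"
            )
    frags: list[Fragment] = []
    if part.circular:
        double = seq + seq
        for i, t in enumerate(cuts):
            t2 = cuts[(i + 1) % len(cuts)]
            if t2 <= t:
                t2 += n
            if t2 - t < ov:
                raise GeometryError(
                    f"part {part.id}: overlapping cut sites at {t}/{t2 % n}"
                )
            span = double[t:t2 + ov]
            frags.append(Fragment(
                span, span[:ov], span[-ov:], part.id,
                _shift_annotations(part.annotations, t, t2 + ov, n, True),
            ))
    else:
        bounds = [0] + cuts + [n]
        for i in range(len(bounds) - 1):
            a, b = bounds[i], bounds[i + 1]
            left_ov = seq[a:a + ov] if a in cuts else ""
            right_ov = seq[b:b + ov] if b in cuts else ""
            end = b + ov if b in cuts else b
            if end - a < len(left_ov):
                raise GeometryError(f"part {part.id}: overlapping cut sites")
            span = seq[a:end]
            frags.append(Fragment(
                span, left_ov, right_ov, part.id,
                _shift_annotations(part.annotations, a, end, n, False),
            ))
    return frags


def ligate(fragments: list[Fragment], start: int = 0) -> AssemblyResult:
    """Ligate fragments into a single circular product.

    Builds the overhang-matching graph and succeeds only if a unique
    Hamiltonian cycle covers every fragment.  Any overhang shared by two
    fragment 5' ends is ambiguous; failures are reported as diagnostics,
    never exceptions.
    """
    if not fragments:
        raise ValueError("at least one fragment required")
    diagnostics: list[str] = []
    five_ends: dict[str, list[int]] = {}
    for i, f in enumerate(fragments):
        if not f.five_overhang or not f.three_overhang:
            diagnostics.append(f"fragment from {f.origin_part} has a blunt end")
        five_ends.setdefault(f.five_overhang, []).append(i)
    for ovh, idxs in five_ends.items():
        if len(idxs) > 1:
            parts = [fragments[i].origin_part for i in idxs]
            diagnostics.append(f"ambiguous overhang {ovh} shared by {parts}")
    if diagnostics:
        return AssemblyResult(None, [], diagnostics)

    order = [start]
    used = {start}
    cur = fragments[start]
    joins: list[tuple] = []
    while True:
        nxt_ids = five_ends.get(cur.three_overhang, [])
        if not nxt_ids:
            diagnostics.append(
                f"no fragment matches overhang {cur.three_overhang} "
                f"after {cur.origin_part}"
            )
            return AssemblyResult(None, [], diagnostics)
        nxt = nxt_ids[0]
        joins.append((cur.origin_part, cur.three_overhang))
        if nxt == start:
            break
        if nxt in used:
            diagnostics.append("ligation closed a sub-cycle before using all fragments")
            return AssemblyResult(None, [], diagnostics)
        used.add(nxt)
        order.append(nxt)
        cur = fragments[nxt]
    unused = [fragments[i].origin_part for i in range(len(fragments)) if i not in used]
    if unused:
        diagnostics.append(f"unused fragments from: {unused}")
        return AssemblyResult(None, [], diagnostics)

    seq_parts: list[str] = []
    annotations: list[tuple] = []
    offset = 0
    for j, i in enumerate(order):
        f = fragments[i]
        chunk = f.sequence if j == 0 else f.sequence[len(f.five_overhang):]
        base = offset - (0 if j == 0 else len(f.five_overhang))
        for (label, s, e, strand) in f.annotations:
            annotations.append((label, s + base, e + base, strand))
        seq_parts.append(chunk)
        offset += len(chunk)
    product = "".join(seq_parts)
    ov = len(fragments[start].five_overhang)
    product = product[:-ov] if ov else product  # closing join: drop duplicate region
    return AssemblyResult(product, joins, [], annotations)


def _residual_sites(product: str, enzymes) -> list[str]:
    double = product + product  # circular
    found = []
    for enz in enzymes:
        for motif in (enz.recognition, reverse_complement(enz.recognition)):
            for p in range(len(product)):
                if double[p:p + len(motif)] == motif:
                    found.append(f"residual {enz.name} site at {p}")
    return found


def _has_label(frag: Fragment, labels: frozenset[str]) -> bool:
    return any(lab.lower() in labels for (lab, *_rest) in frag.annotations)


def simulate_reaction(accepter, inserts, enzymes) -> AssemblyResult:
    """One-pot GoldenGate: digest accepter + inserts, select, ligate, verify.

    The accepter's backbone is the digestion fragment lacking a dropout
    marker (LacZ / RFP); each insert contributes the fragment free of its
    own vector-backbone annotation.  ``inserts`` may contain PartRecords or
    preformed Fragments (annealed oligo duplexes).  The product is checked
    for residual recognition sites of the reaction enzymes — GoldenGate
    assembly must be irreversible.
    """
    enzymes = [ENZYMES[e] if isinstance(e, str) else e for e in enzymes]
    diagnostics: list[str] = []

    acc_frags = digest(accepter, enzymes)
    backbone = [f for f in acc_frags if not _has_label(f, DROPOUT_LABELS)]
    if len(acc_frags) == 1:
        diagnostics.append(f"accepter {accepter.id} was not cut by {[e.name for e in enzymes]}")
    if len(backbone) != 1:
        diagnostics.append(
            f"accepter {accepter.id}: expected exactly one backbone fragment, "
            f"got {len(backbone)}"
        )
        return AssemblyResult(None, [], diagnostics)

    selected: list[Fragment] = backbone
    for ins in inserts:
        if isinstance(ins, Fragment):
            selected.append(ins)
            continue
        frags = digest(ins, enzymes)
        keep = [
            f for f in frags
            if not _has_label(f, BACKBONE_LABELS | DROPOUT_LABELS)
        ]
        if len(frags) == 1:
            diagnostics.append(f"insert {ins.id} was not cut")
        if len(keep) != 1:
            diagnostics.append(
                f"insert {ins.id}: expected exactly one cassette fragment, "
                f"got {len(keep)}"
            )
            continue
        selected.append(keep[0])
    if diagnostics:
        return AssemblyResult(None, [], diagnostics)

    result = ligate(selected, start=0)
    if result.product is not None:
        for msg in _residual_sites(result.product, enzymes):
            result.diagnostics.append(msg)
    return result


def simulate_plan(plan, parts: dict) -> dict[str, AssemblyResult]:
    """Run every step of an :class:`~cerealcas.assembly_planner.AssemblyPlan`
    over a dictionary of parts, feeding intermediate products forward.

    Returns step products keyed by module id ("L1_<label>", "LM_<i>",
    "L2").  Raises KeyError if a required part is missing.
    """
    pool: dict = dict(parts)
    results: dict[str, AssemblyResult] = {}

    def as_part(obj, pid: str):
        if isinstance(obj, (PartRecord, Fragment)):
            return obj
        raise TypeError(f"{pid}: not a part")

    for step in plan.steps:
        missing = [i for i in (step.accepter_id, *step.insert_ids) if i not in pool]
        if missing:
            res = AssemblyResult(None, [], [f"missing input part/product: {missing}"])
        else:
            accepter = as_part(pool[step.accepter_id], step.accepter_id)
            inserts = [as_part(pool[i], i) for i in step.insert_ids]
            res = simulate_reaction(accepter, inserts, step.enzymes)
        if step.level == "L1":
            label = step.insert_ids[0].removeprefix("oligos_")
            pid = f"L1_{label}"
        elif step.level == "LM":
            pid = step.accepter_id.replace("LM_accepter_", "LM_")
        else:
            pid = "L2"
        results[pid] = res
        if res.product is not None:
            pool[pid] = PartRecord(
                pid, res.product, circular=True, role="insert",
                annotations=list(res.annotations),
            )
    return results


def part_to_seqrecord(part: PartRecord) -> SeqRecord:
    """PartRecord -> Biopython SeqRecord with features, for GenBank output."""
    rec = SeqRecord(Seq(part.sequence), id=part.id, name=part.id[:16],
                    description=f"role={part.role}")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if part.circular else "linear"
    for (label, s, e, strand) in part.annotations:
        rec.features.append(SeqFeature(
            FeatureLocation(int(s), int(e), strand=1 if strand == "+" else -1),
            type="misc_feature", qualifiers={"label": [label]},
        ))
    return rec


def seqrecord_to_part(rec: SeqRecord, role: str = "insert") -> PartRecord:
    annotations = []
    for feat in rec.features:
        label = feat.qualifiers.get("label", [feat.type])[0]
        strand = "+" if (feat.location.strand or 1) >= 0 else "-"
        annotations.append((label, int(feat.location.start),
                            int(feat.location.end), strand))
    circular = rec.annotations.get("topology", "linear") == "circular"
    return PartRecord(rec.id, str(rec.seq), circular, role, annotations)
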