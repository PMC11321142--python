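"""Synthetic data generators: references, edited amplicon reads, T0 cohorts
and toy GoldenGate parts.

Everything here is seed-deterministic and built programmatically so the
rest of the package is testable without any downloaded data.  The read
simulator emulates the structure of paired-end amplicon sequencing of
CRISPR target loci (defined indel patterns at a cut site at controlled
frequencies); the cohort simulator emulates T0 plant populations with
either nested or independent per-gene editing outcomes.  The part factory
fabricates minimal accepter plasmids with self-consistent fusion-site
overhangs so that any assembly plan can be simulated end to end; the
overhang sequences between positions are invented (the physical toolkit
plasmids define their own) and the factory tailors accepter ends to each
plan, which subsumes the role of physical end linkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .guide_design import ARCHITECTURES, Nuclease, design_oligo_pair, reverse_complement
from .assembly_sim import Fragment, PartRecord
from .amplicon_caller import IndelPattern, LocusSpec

__all__ = [
    "EditProfile",
    "CohortProfile",
    "make_reference",
    "simulate_edited_reads",
    "simulate_t0_cohort",
    "simulate_allele_percentages",
    "build_parts_for_plan",
    "quota_counts",
]


# ---------------------------------------------------------------------------
# references

def make_reference(length: int, gc_fraction: float, seed: int,
                   seq_id: str = "ref") -> SeqRecord:
    """Random DNA with an exact GC quota (shuffled), as a FASTA record.

    The GC count is fixed at ``round(gc_fraction * length)`` so the
    composition is exact, not merely expected.
    """
    if length < 100:
        raise ValueError("reference length must be >= 100")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_gc = round(gc_fraction * length)
    n_at = length - n_gc
    bases = np.concatenate([
        rng.choice(list("GC"), n_gc),
        rng.choice(list("AT"), n_at),
    ])
    rng.shuffle(bases)
    return SeqRecord(Seq("".join(bases)), id=seq_id, description="")


# ---------------------------------------------------------------------------
# amplicon read simulation

@dataclass(frozen=True)
class EditProfile:
    """Mixture of indel patterns for one simulated amplicon sample.

    ``patterns`` maps each :class:`IndelPattern` to its frequency; together
    with ``wt_frequency`` the frequencies must sum to 1.  Pattern counts are
    allocated by quota (largest remainder), so small-n truths are exact.
    """

    patterns: tuple          # ((IndelPattern, frequency), ...)
    wt_frequency: float
    n_pairs: int
    seed: int
    substitution_error_rate: float = 0.0
    read_length: int = 150
    off_boundary_fraction: float = 0.0

    def __post_init__(self) -> None:
        total = self.wt_frequency + sum(f for _, f in self.patterns)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, expected 1")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


def quota_counts(freqs, n: int) -> list[int]:
    """Largest-remainder apportionment of n among frequencies."""
    raw = [f * n for f in freqs]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(freqs)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _apply_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        out[i] = others[out[i]][rng.integers(3)]
    return "".join(out)


def _mate1_read(ref: str, start: int, rl: int, pattern: IndelPattern, rng):
    """Read sequence and CIGAR for the forward mate carrying ``pattern``."""
    read = []
    cigar = []
    ref_pos = start
    q = 0
    events = list(pattern.events)
    while q < rl:
        nxt = events[0] if events else None
        if nxt is not None and nxt[1] == ref_pos:
            op, pos, length = events.pop(0)
            if op == "D":
                cigar.append((length, "D"))
                ref_pos += length
            else:
                ins = "".join(rng.choice(list("ACGT"), length))
                take = min(length, rl - q)
                read.append(ins[:take])
                cigar.append((take, "I"))
                q += take
            continue
        stop = nxt[1] if nxt is not None else len(ref)
        m = min(stop - ref_pos, rl - q)
        if m <= 0:
            raise ValueError(f"pattern {pattern.key} does not fit in the read")
        read.append(ref[ref_pos:ref_pos + m])
        cigar.append((m, "M"))
        ref_pos += m
        q += m
    cigar_str = "".join(f"{l}{op}" for l, op in cigar)
    return "".join(read), cigar_str


def simulate_edited_reads(locus: LocusSpec, profile: EditProfile):
    """Simulate proper read pairs over an amplicon as SAM text.

    The amplicon runs the full reference; mate 1 starts at the left
    boundary (position 0) and carries the indel pattern, mate 2 starts at
    ``len(reference) - read_length`` and is pure match, mirroring a design
    where the cut site sits in the forward read only.  A configurable
    fraction of (wild-type) pairs starts off-boundary, emulating mispriming
    — those are exactly the pairs the boundary filter should drop.

    Returns ``(sam_text, truth)`` where ``truth`` maps pair id to the
    pattern key ("" for wild type).
    """
    ref = locus.reference
    rl = profile.read_length
    if len(ref) < rl + 20:
        raise ValueError("reference too short for the requested read length")
    b1, b2 = 0, len(ref) - rl
    for pat, _f in profile.patterns:
        for op, pos, length in pat.events:
            end = pos + (length if op == "D" else 0)
            if not (b1 < pos and end < b1 + rl - 1):
                raise ValueError(
                    f"pattern event {op}:{pos}:{length} outside the forward "
                    f"read span (1..{b1 + rl - 2})"
                )
    rng = np.random.default_rng(profile.seed)
    groups = [(None, profile.wt_frequency)] + list(profile.patterns)
    counts = quota_counts([f for _, f in groups], profile.n_pairs)
    n_off = round(profile.off_boundary_fraction * profile.n_pairs)

    header = (
        "@HD\tVN:1.6\tSO:unsorted\n"
        f"@SQ\tSN:{locus.locus_id}\tLN:{len(ref)}\n"
        "@PG\tID:cerealcas\tPN:cerealcas\n"
    )
    lines = []
    truth: dict[str, str] = {}
    pair_no = 0
    for (pattern, _freq), count in zip(groups, counts):
        for _ in range(count):
            pair_no += 1
            pid = f"pair{pair_no:05d}"
            shift = 0
            if pattern is None and n_off > 0:
                shift = int(rng.integers(1, 4))
                n_off -= 1
            if pattern is None:
                seq1 = ref[b1 + shift:b1 + shift + rl]
                cig1 = f"{rl}M"
                truth[pid] = "" if shift == 0 else "off_boundary"
            else:
                seq1, cig1 = _mate1_read(ref, b1, rl, pattern, rng)
                truth[pid] = pattern.key
            seq1 = _apply_errors(seq1, profile.substitution_error_rate, rng)
            seq2 = _apply_errors(ref[b2:b2 + rl], profile.substitution_error_rate, rng)
            q = "I" * rl
            p1 = b1 + shift + 1
            p2 = b2 + 1
            tlen = b2 + rl - (b1 + shift)
            lines.append(
                f"{pid}\t99\t{locus.locus_id}\t{p1}\t60\t{cig1}\t=\t{p2}\t{tlen}\t{seq1}\t{q}"
            )
            lines.append(
                f"{pid}\t147\t{locus.locus_id}\t{p2}\t60\t{rl}M\t=\t{p1}\t{-tlen}\t{seq2}\t{q}"
            )
    return header + "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# T0 cohorts

@dataclass(frozen=True)
class CohortProfile:
    """Per-gene true editing efficiencies for a simulated T0 population.

    ``nesting_model="nested_activity"`` draws one latent competence value
    per plant, a ~ U(0,1), and mutates gene g iff a < e_g.  Outcomes are
    then perfectly nested, so the all-targets rate equals the lowest
    per-gene efficiency — the structure observed in multiplex T0 data.
    ``"independent"`` draws per-gene Bernoulli(e_g) instead.
    """

    genes: tuple             # ((gene_name, efficiency), ...)
    n_plants: int
    seed: int
    nesting_model: str = "nested_activity"
    construct: str = "construct1"

    def __post_init__(self) -> None:
        for g, e in self.genes:
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"efficiency for {g} outside [0, 1]")
        if self.nesting_model not in ("nested_activity", "independent"):
            raise ValueError(f"unknown nesting model {self.nesting_model!r}")


def simulate_t0_cohort(profile: CohortProfile):
    """T0 outcome table (plant_id, construct, gene, mutated) as a DataFrame."""
    import pandas as pd

    rng = np.random.default_rng(profile.seed)
    rows = []
    for i in range(profile.n_plants):
        pid = f"{profile.construct}_plant{i + 1:03d}"
        if profile.nesting_model == "nested_activity":
            a = rng.random()
            flags = {g: a < e for g, e in profile.genes}
        else:
            flags = {g: rng.random() < e for g, e in profile.genes}
        for g, _e in profile.genes:
            rows.append((pid, profile.construct, g, bool(flags[g])))
    return pd.DataFrame(rows, columns=["plant_id", "construct", "gene", "mutated"])


def simulate_allele_percentages(cell_means: dict, n_per_cell: int, sd: float,
                                seed: int):
    """Per-plant mutant-allele percentages for a crossed (gene, variant)
    design: normal noise around the given cell means, clipped to [0, 100].

    ``cell_means`` maps (gene, variant) -> mean percentage.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for (gene, variant), mu in cell_means.items():
        vals = np.clip(rng.normal(mu, sd, n_per_cell), 0.0, 100.0)
        for j, v in enumerate(vals):
            rows.append((f"{variant}_{gene}_p{j + 1}", variant, gene, float(v)))
    return pd.DataFrame(
        rows, columns=["plant_id", "construct", "gene", "pct_mutant_alleles"]
    )


# ---------------------------------------------------------------------------
# GoldenGate toy parts

_GFREE = "ACT"  # fillers avoid G so no BsaI/BpiI motif can occur in them

#: overhang regions reserved by the level-1 oligo templates
_RESERVED = {
    a.fwd_overhang for a in ARCHITECTURES.values()
} | {reverse_complement(a.rev_overhang) for a in ARCHITECTURES.values()}


def _overhang_pool():
    from itertools import product

    for combo in product(_GFREE, repeat=4):
        ov = "".join(combo)
        if ov not in _RESERVED and ov != reverse_complement(ov):
            yield ov


def _filler(rng, length: int) -> str:
    return "".join(rng.choice(list(_GFREE), length))


def _assert_clean(part: PartRecord, expected_bsai: int, expected_bpii: int) -> None:
    seq2 = part.sequence * 2
    n = len(part.sequence)
    for motif, expected in (("GGTCTC", expected_bsai), ("GAAGAC", expected_bpii)):
        rc = reverse_complement(motif)
        count = sum(
            1 for p in range(n)
            if seq2[p:p + 6] in (motif, rc)
        )
        if count != expected:
            raise AssemblyFixtureError(
                f"{part.id}: {count} {motif}-class sites, expected {expected}"
            )


class AssemblyFixtureError(RuntimeError):
    pass


_TYPEIIS_MOTIFS = ("GGTCTC", "GAGACC", "GAAGAC", "GTCTTC")


def random_protospacer(rng, architecture, length: int | None = None) -> str:
    """Random protospacer free of internal/junction BsaI and BpiI sites.

    GoldenGate cloning requires domesticated protospacers: a recognition
    site inside the oligo (or formed at its junction with the accepter)
    would be re-cut during assembly.  Rejection-samples until the
    protospacer, embedded in its architecture's overhang context, carries
    no type-IIS motif on either strand.
    """
    if isinstance(architecture, Nuclease):
        archs = [a for a in ARCHITECTURES.values() if a.nuclease is architecture]
    elif isinstance(architecture, str):
        archs = [ARCHITECTURES[architecture]]
    else:
        archs = [architecture]
    if length is None:
        length = 20 if archs[0].nuclease is Nuclease.CAS9 else 23
    while True:
        proto = "".join(rng.choice(list("ACGT"), length))
        clean = all(
            not any(
                m in "AA" + a.fwd_overhang + proto
                + reverse_complement(a.rev_overhang) + "AA"
                for m in _TYPEIIS_MOTIFS
            )
            for a in archs
        )
        if clean:
            return proto


def _l1_accepter(accepter_id, arch, e_left, e_right, rng) -> PartRecord:
    """Circular level-1 guide accepter: BsaI sites flank a LacZ dropout that
    the oligo duplex replaces; BpiI sites flank the whole cassette for
    release into the next level."""
    fwd = arch.fwd_overhang
    rc_rev = reverse_complement(arch.rev_overhang)
    backbone = _filler(rng, 80)
    # the two bases flanking the cloning site are pinned so that the
    # domestication check in random_protospacer sees the exact junction
    # context the cassette will have
    promoter = _filler(rng, 28) + "AA"
    lacz = _filler(rng, 50)
    scaffold = "AA" + _filler(rng, 28)
    pieces = [
        ("backbone", backbone),
        (None, "GAAGAC" + "AA" + e_left),
        ("promoter", promoter),
        (None, fwd + "A" + "GAGACC"),
        ("LacZ", lacz),
        (None, "GGTCTC" + "A" + rc_rev),
        ("scaffold", scaffold),
        (None, e_right + "AA" + "GTCTTC"),
    ]
    seq = ""
    annotations = []
    for label, chunk in pieces:
        if label:
            annotations.append((label, len(seq), len(seq) + len(chunk), "+"))
        seq += chunk
    part = PartRecord(accepter_id, seq, circular=True, role="accepter",
                      annotations=annotations)
    _assert_clean(part, expected_bsai=2, expected_bpii=2)
    return part


def _stacking_accepter(accepter_id, open_left, open_right, release_left,
                       release_right, open_enzyme, release_enzyme,
                       rng, dropout_label) -> PartRecord:
    """Circular stacking accepter (level M or level 2).

    ``open_*`` are the overhangs exposed when the dropout is excised by
    ``open_enzyme``; ``release_*`` (may be None for level 2) are the ends
    the *next* level's ``release_enzyme`` will expose around the stacked
    array.
    """
    sites = {
        "BsaI": ("GGTCTC", "GAGACC", 1),
        "BpiI": ("GAAGAC", "GTCTTC", 2),
    }
    o_fwd, o_rev, o_sp = sites[open_enzyme]
    backbone = _filler(rng, 100)
    dropout = _filler(rng, 50)
    pieces = [("backbone", backbone)]
    if release_left is not None:
        r_fwd, r_rev, r_sp = sites[release_enzyme]
        pieces.append((None, r_fwd + "A" * r_sp + release_left))
    pieces.extend([
        (None, open_left + "A" * o_sp + o_rev),
        (dropout_label, dropout),
        (None, o_fwd + "A" * o_sp + open_right),
    ])
    if release_right is not None:
        pieces.append((None, release_right + "A" * r_sp + r_rev))
    seq = ""
    annotations = []
    for label, chunk in pieces:
        if label:
            annotations.append((label, len(seq), len(seq) + len(chunk), "+"))
        seq += chunk
    part = PartRecord(accepter_id, seq, circular=True, role="accepter",
                      annotations=annotations)
    n_bsai = (2 if open_enzyme == "BsaI" else 0) + \
        (2 if release_left is not None and release_enzyme == "BsaI" else 0)
    n_bpii = (2 if open_enzyme == "BpiI" else 0) + \
        (2 if release_left is not None and release_enzyme == "BpiI" else 0)
    _assert_clean(part, expected_bsai=n_bsai, expected_bpii=n_bpii)
    return part


def build_parts_for_plan(plan, guides, seed: int = 0) -> dict:
    """Fabricate every part a plan needs: oligo duplexes, level-1 guide
    accepters with plan-consistent release overhangs, level-M stacking
    accepters and the level-2 binary accepter.

    Overhang series are invented but globally distinct, so each reaction's
    ligation is unambiguous.  Returns a dict keyed by the plan's part ids,
    ready for :func:`cerealcas.assembly_sim.simulate_plan`.
    """
    rng = np.random.default_rng(seed)
    pool = _overhang_pool()
    by_label = {g.label: g for g in guides}
    promoter_of = dict(zip(plan.guide_labels, plan.promoter_assignment))

    l2_step = next(s for s in plan.steps if s.level == "L2")
    lm_steps = {s.accepter_id.replace("LM_accepter_", "LM_"): s
                for s in plan.steps if s.level == "LM"}
    m = len(l2_step.insert_ids)
    s_series = [next(pool) for _ in range(m + 1)]
    # level-M position overhangs are one shared series: every level-M vector
    # uses the same per-position fusion sites, like the physical toolkit
    max_lm = max((len(s.insert_ids) for s in lm_steps.values()), default=0)
    t_series = [next(pool) for _ in range(max_lm + 1)]

    # where does each L1 module end up, and with which flanking overhangs?
    l1_ends: dict[str, tuple[str, str]] = {}
    for j, mod in enumerate(l2_step.insert_ids):
        if mod.startswith("LM_"):
            for i, l1_id in enumerate(lm_steps[mod].insert_ids):
                l1_ends[l1_id] = (t_series[i], t_series[i + 1])
        else:
            l1_ends[mod] = (s_series[j], s_series[j + 1])

    parts: dict = {}
    for step in plan.steps:
        if step.level == "L1":
            label = step.insert_ids[0].removeprefix("oligos_")
            g = by_label[label]
            if g.nuclease is Nuclease.CAS9:
                arch = ARCHITECTURES[f"CAS9_A_{promoter_of[label]}"]
            else:
                arch = ARCHITECTURES[f"CAS12A_{g.architecture_family}"]
            pair = design_oligo_pair(g.protospacer, arch)
            parts[f"oligos_{label}"] = Fragment(
                sequence=arch.fwd_overhang + pair.protospacer
                + reverse_complement(arch.rev_overhang),
                five_overhang=arch.fwd_overhang,
                three_overhang=reverse_complement(arch.rev_overhang),
                origin_part=f"oligos_{label}",
            )
            e_l, e_r = l1_ends[f"L1_{label}"]
            parts[step.accepter_id] = _l1_accepter(
                step.accepter_id, arch, e_l, e_r, rng)
        elif step.level == "LM":
            lm_id = step.accepter_id.replace("LM_accepter_", "LM_")
            j = l2_step.insert_ids.index(lm_id)
            parts[step.accepter_id] = _stacking_accepter(
                step.accepter_id,
                open_left=t_series[0],
                open_right=t_series[len(step.insert_ids)],
                release_left=s_series[j], release_right=s_series[j + 1],
                open_enzyme="BpiI", release_enzyme="BsaI",
                rng=rng, dropout_label="LacZ",
            )
        else:
            parts[step.accepter_id] = _stacking_accepter(
                step.accepter_id,
                open_left=s_series[0], open_right=s_series[-1],
                release_left=None, release_right=None,
                open_enzyme="BsaI", release_enzyme="BsaI",
                rng=rng, dropout_label="RFP",
            )
    return parts
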