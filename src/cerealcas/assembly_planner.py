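"""GoldenGate cloning plans: vector choice, promoter alternation and routing.

The toolkit assembles guide expression cassettes hierarchically:

* level 1 — oligo pair cloned into a guide accepter (BsaI);
* level M — optional intermediate stacking of up to 4 level-1 cassettes
  (BpiI), used whenever more than 4 guides are needed;
* level 2 — the final binary (T-DNA) vector combining up to 4 modules
  (level-1 cassettes or level-M stacks) with the nuclease cassette
  (BsaI & BpiI in one pot).

Enzymes per step:

====================  ==============
cloning step          enzymes
====================  ==============
oligos -> level 1     BsaI
level 1 -> level 2    BsaI & BpiI
level 1 -> level M    BpiI
level M -> level 2    BsaI & BpiI
====================  ==============

The binary-vector catalogue is species- and nuclease-specific; wheat
vectors additionally come with constitutive (GRF-GIF) or
dexamethasone-inducible (GR-GRF-GIF) transformation-booster options.
When stacking tandem guide arrays it is good practice to alternate
U6-class and U3-class pol III promoters to avoid bacterial recombination
between repeats; :func:`assign_promoters` implements that rule.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .guide_design import Nuclease

__all__ = [
    "Species",
    "GrfOption",
    "GuideRequest",
    "PlannerConfig",
    "AssemblyStep",
    "AssemblyPlan",
    "BINARY_VECTORS",
    "MAX_GUIDES",
    "NoVectorError",
    "CapacityError",
    "choose_binary_vector",
    "assign_promoters",
    "plan",
    "plan_to_json",
    "plan_to_protocol",
]

#: toolkit capacity: number of guides supported in one final level-2 assembly
MAX_GUIDES = 26

#: GoldenGate positions available in a level-2 (or level-M) accepter
L2_POSITIONS = 7

U6_CLASS = ("TaU6",)
U3_CLASS = ("TaU3", "HvU3")
PROMOTERS = U6_CLASS + U3_CLASS

STEP_ENZYMES = {
    "L1": frozenset({"BsaI"}),
    "LM": frozenset({"BpiI"}),
    "L2": frozenset({"BsaI", "BpiI"}),
}


class Species(str, Enum):
    BARLEY = "barley"
    WHEAT = "wheat"


class GrfOption(str, Enum):
    NONE = "none"
    GRF_GIF = "GRF_GIF"
    GR_GRF_GIF = "GR_GRF_GIF"


#: (species, cas9, cas12a, grf_option) -> EC vector id
BINARY_VECTORS: dict[tuple[Species, bool, bool, GrfOption], str] = {
    (Species.BARLEY, True, False, GrfOption.NONE): "EC64420",
    (Species.BARLEY, False, True, GrfOption.NONE): "EC67842",
    (Species.BARLEY, True, True, GrfOption.NONE): "EC64434",
    (Species.WHEAT, True, False, GrfOption.NONE): "EC67844",
    (Species.WHEAT, True, False, GrfOption.GRF_GIF): "EC70364",
    (Species.WHEAT, True, False, GrfOption.GR_GRF_GIF): "EC67907",
    (Species.WHEAT, False, True, GrfOption.NONE): "EC67843",
    (Species.WHEAT, False, True, GrfOption.GRF_GIF): "EC67841",
    (Species.WHEAT, False, True, GrfOption.GR_GRF_GIF): "EC67908",
}


class NoVectorError(ValueError):
    """No binary vector exists for the requested configuration."""


class CapacityError(ValueError):
    """More guides requested than the toolkit supports."""


@dataclass(frozen=True)
class GuideRequest:
    label: str
    protospacer: str
    nuclease: Nuclease
    architecture_family: str  # "A", "V2" or "V3"
    promoter_preference: str | None = None

    def __post_init__(self) -> None:
        fam = self.architecture_family
        if fam not in ("A", "V2", "V3"):
            raise ValueError(f"unknown architecture family {fam!r}")
        if fam == "A" and self.nuclease is not Nuclease.CAS9:
            raise ValueError("architecture family A is Cas9-only")
        if fam in ("V2", "V3") and self.nuclease is not Nuclease.CAS12A:
            raise ValueError(f"architecture family {fam} is Cas12a-only")
        if self.promoter_preference is not None and \
                self.promoter_preference not in PROMOTERS:
            raise ValueError(f"unknown promoter {self.promoter_preference!r}")

    @property
    def architecture_name(self) -> str:
        if self.nuclease is Nuclease.CAS9:
            return f"CAS9_A_{{promoter}}"
        return f"CAS12A_{self.architecture_family}"


@dataclass(frozen=True)
class PlannerConfig:
    species: Species
    use_cas9: bool = False
    use_cas12a: bool = False
    grf_option: GrfOption = GrfOption.NONE
    max_inserts_per_step: int = 4

    def __post_init__(self) -> None:
        if not (self.use_cas9 or self.use_cas12a):
            raise ValueError("at least one of use_cas9/use_cas12a must be set")
        if self.max_inserts_per_step < 1:
            raise ValueError("max_inserts_per_step must be >= 1")


@dataclass(frozen=True)
class AssemblyStep:
    level: str                      # "L1", "LM" or "L2"
    accepter_id: str
    insert_ids: tuple[str, ...]
    enzymes: frozenset[str]
    position_index: int             # GoldenGate position within the destination

    def __post_init__(self) -> None:
        if self.level not in STEP_ENZYMES:
            raise ValueError(f"unknown level {self.level!r}")
        if self.enzymes != STEP_ENZYMES[self.level]:
            raise ValueError(
                f"{self.level} step must use enzymes {set(STEP_ENZYMES[self.level])}"
            )


@dataclass(frozen=True)
class AssemblyPlan:
    steps: tuple[AssemblyStep, ...]
    binary_vector: str
    promoter_assignment: tuple[str, ...]   # parallel to the guide list
    guide_labels: tuple[str, ...]


def choose_binary_vector(config: PlannerConfig) -> str:
    """Pick the unique level-2 binary vector matching the configuration."""
    key = (config.species, config.use_cas9, config.use_cas12a, config.grf_option)
    try:
        return BINARY_VECTORS[key]
    except KeyError:
        near = sorted(
            vec for (sp, c9, c12, _grf), vec in BINARY_VECTORS.items()
            if sp == config.species
        )
        raise NoVectorError(
            f"no binary vector for species={config.species.value}, "
            f"Cas9={config.use_cas9}, Cas12a={config.use_cas12a}, "
            f"GRF option={config.grf_option.value}; vectors available for "
            f"{config.species.value}: {near}"
        ) from None


def _promoter_class(p: str) -> str:
    return "U6" if p in U6_CLASS else "U3"


def assign_promoters(guides: Sequence[GuideRequest]) -> list[str]:
    """Assign pol III promoters along the tandem array, alternating classes.

    Explicit ``promoter_preference`` values are honoured; unconstrained
    guides cycle U6-class / U3-class so that no two adjacent cassettes share
    a promoter class.  If preferences force an adjacent same-class pair a
    warning is emitted (the assignment is still returned).
    """
    if not guides:
        raise ValueError("no guides to assign promoters to")
    assignment: list[str] = []
    for g in guides:
        if g.promoter_preference is not None:
            assignment.append(g.promoter_preference)
            continue
        prev_class = _promoter_class(assignment[-1]) if assignment else None
        if prev_class == "U6":
            # alternate within the U3 class too (TaU3 / HvU3) to minimise
            # repeated promoter sequence in long arrays
            n_u3 = sum(1 for p in assignment if p in U3_CLASS)
            assignment.append(U3_CLASS[n_u3 % len(U3_CLASS)])
        else:
            assignment.append(U6_CLASS[0])
    clashes = [
        i for i in range(1, len(assignment))
        if _promoter_class(assignment[i]) == _promoter_class(assignment[i - 1])
    ]
    if clashes:
        warnings.warn(
            f"promoter preferences force adjacent same-class promoters at "
            f"array positions {clashes}; consider reordering guides",
            stacklevel=2,
        )
    return assignment


def _pack(labels: Sequence[str], size: int) -> list[list[str]]:
    """Greedy fill-to-capacity packing preserving order."""
    return [list(labels[i:i + size]) for i in range(0, len(labels), size)]


def plan(guides: Sequence[GuideRequest], config: PlannerConfig) -> AssemblyPlan:
    """Produce the ordered GoldenGate plan for a set of guide requests.

    With <= ``max_inserts_per_step`` guides per nuclease sub-array, level-1
    cassettes go straight into the level-2 binary vector; larger arrays are
    greedily packed into level-M stacks of up to 4 first.  Dual-nuclease
    builds keep the Cas9 and Cas12a guides as two independent sub-arrays.
    """
    if not guides:
        raise ValueError("at least one guide is required")
    labels = [g.label for g in guides]
    if len(set(labels)) != len(labels):
        raise ValueError("guide labels must be unique")
    if len(guides) > MAX_GUIDES:
        raise CapacityError(
            f"{len(guides)} guides requested but the toolkit supports at "
            f"most {MAX_GUIDES} in one level-2 assembly"
        )
    for g in guides:
        if g.nuclease is Nuclease.CAS9 and not config.use_cas9:
            raise ValueError(f"guide {g.label!r} needs Cas9 but use_cas9 is off")
        if g.nuclease is Nuclease.CAS12A and not config.use_cas12a:
            raise ValueError(f"guide {g.label!r} needs Cas12a but use_cas12a is off")

    binary_vector = choose_binary_vector(config)
    promoters = assign_promoters(guides)
    cap = config.max_inserts_per_step

    # independent sub-arrays per nuclease, in stable nuclease order
    sub_arrays: list[list[GuideRequest]] = []
    for nuc in (Nuclease.CAS9, Nuclease.CAS12A):
        sub = [g for g in guides if g.nuclease is nuc]
        if sub:
            sub_arrays.append(sub)

    # a sub-array longer than the per-step cap must go via level M; if the
    # combined direct inserts would exceed the seven GoldenGate positions of
    # the level-2 accepter, every multi-guide sub-array goes via level M too
    via_lm = [len(sub) > cap for sub in sub_arrays]
    def _l2_count() -> int:
        return sum(
            math.ceil(len(sub) / cap) if lm else len(sub)
            for sub, lm in zip(sub_arrays, via_lm)
        )
    if _l2_count() > L2_POSITIONS:
        via_lm = [len(sub) > 1 for sub in sub_arrays]
    if _l2_count() > L2_POSITIONS:
        raise CapacityError(
            f"{len(guides)} guides cannot be routed into the "
            f"{L2_POSITIONS} level-2 positions even via level M"
        )

    steps: list[AssemblyStep] = []
    l2_inserts: list[str] = []
    lm_index = 0

    for sub, lm in zip(sub_arrays, via_lm):
        l1_ids = [f"L1_{g.label}" for g in sub]
        if not lm:
            # direct route: L1 cassettes feed level 2
            for pos, g in enumerate(sub, start=1):
                slot = len(l2_inserts) + pos
                steps.append(AssemblyStep(
                    "L1",
                    accepter_id=_l1_accepter_id(g, promoters, guides, "p", slot),
                    insert_ids=(f"oligos_{g.label}",),
                    enzymes=STEP_ENZYMES["L1"],
                    position_index=slot,
                ))
            l2_inserts.extend(l1_ids)
        else:
            groups = _pack(l1_ids, cap)
            flat = 0
            for group in groups:
                for pos_in_group in range(1, len(group) + 1):
                    g = sub[flat]
                    steps.append(AssemblyStep(
                        "L1",
                        accepter_id=_l1_accepter_id(g, promoters, guides,
                                                    "m", pos_in_group),
                        insert_ids=(f"oligos_{g.label}",),
                        enzymes=STEP_ENZYMES["L1"],
                        position_index=pos_in_group,
                    ))
                    flat += 1
            for group in groups:
                lm_index += 1
                steps.append(AssemblyStep(
                    "LM", accepter_id=f"LM_accepter_{lm_index}",
                    insert_ids=tuple(group),
                    enzymes=STEP_ENZYMES["LM"],
                    position_index=len(l2_inserts) + 1,
                ))
                l2_inserts.append(f"LM_{lm_index}")

    steps.append(AssemblyStep(
        "L2", accepter_id=binary_vector,
        insert_ids=tuple(l2_inserts),
        enzymes=STEP_ENZYMES["L2"],
        position_index=1,
    ))
    return AssemblyPlan(
        steps=tuple(steps),
        binary_vector=binary_vector,
        promoter_assignment=tuple(promoters),
        guide_labels=tuple(g.label for g in guides),
    )


def _l1_accepter_id(g: GuideRequest, promoters: Sequence[str],
                    guides: Sequence[GuideRequest], route: str,
                    position: int) -> str:
    # accepters are position-specific parts ("p" = direct-to-level-2 slot,
    # "m" = slot within a level-M stack), matching the toolkit's
    # promoter x position accepter matrix
    promoter = promoters[list(guides).index(g)]
    if g.nuclease is Nuclease.CAS9:
        return f"L1_accepter_CAS9_A_{promoter}_{route}{position}"
    return f"L1_accepter_CAS12A_{g.architecture_family}_{promoter}_{route}{position}"


def plan_to_json(p: AssemblyPlan) -> str:
    """Serialise a plan as JSON (steps, accepters, enzymes, positions, vector)."""
    return json.dumps(
        {
            "binary_vector": p.binary_vector,
            "guide_labels": list(p.guide_labels),
            "promoter_assignment": list(p.promoter_assignment),
            "steps": [
                {
                    "level": s.level,
                    "accepter": s.accepter_id,
                    "inserts": list(s.insert_ids),
                    "enzymes": sorted(s.enzymes),
                    "position": s.position_index,
                }
                for s in p.steps
            ],
        },
        indent=2,
    )


def plan_to_protocol(p: AssemblyPlan, oligos=None) -> str:
    """Human-readable bench protocol (Markdown) for a plan.

    ``oligos`` may map guide label -> OligoPair to include ordering sequences.
    """
    lines = [f"# GoldenGate assembly plan ({p.binary_vector})", ""]
    if oligos:
        lines.append("## Oligos to order")
        lines.append("")
        for label, pair in oligos.items():
            lines.append(f"- {label}: F `{pair.forward}` / R `{pair.reverse}`")
        lines.append("")
    for level, title in (("L1", "Level 1 (oligos -> guide accepters, BsaI)"),
                         ("LM", "Level M (stacking, BpiI)"),
                         ("L2", "Level 2 (final binary vector, BsaI & BpiI)")):
        steps = [s for s in p.steps if s.level == level]
        if not steps:
            continue
        lines.append(f"## {title}")
        lines.append("")
        for s in steps:
            lines.append(
                f"- position {s.position_index}: {', '.join(s.insert_ids)} "
                f"into {s.accepter_id} ({' + '.join(sorted(s.enzymes))})"
            )
        lines.append("")
    lines.append("Alternate U6/U3-class promoters along arrays: "
                 + " | ".join(p.promoter_assignment))
    return "\n".join(lines)
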