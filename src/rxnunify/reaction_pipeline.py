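"""Reaction preprocessing, stoichiometric QC and direction-agnostic keys.

Order of operations for reconciliation:

1. alias application and NAD(P)(H)-placeholder splitting;
2. stoichiometry check — *before* water/proton removal, on the
   neutral-parent formulas of each participant's compound class;
3. removal of water and protons from both sides (databases disagree on
   writing them, and many deposited equations are not balanced);
4. the reaction key: both sides as sorted multisets of
   (compound class, coefficient), the two sides themselves ordered
   canonically so that a reaction and its reverse writing collide.

The balance check tolerates a deficit of whole protons and/or waters
on one side (``balanced_tolerated``); any other deficit marks the
reaction ``incomplete``, with the missing atoms reported per side
(Missing Substrate / Missing Product).  Participants without a formula
(generic compounds) or with symbolic coefficients make the status
``undetermined``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

from .chem_norm import ElementCounts, WATER_KEY, counts_to_formula
from .io_model import (
    ARROW_DIRECTIONS,
    CompoundRecord,
    Participant,
    ReactionRecord,
    Ref,
    SourceDump,
)
from .name_norm import normalize_name

log = logging.getLogger(__name__)

__all__ = [
    "parse_equation",
    "split_nadp_placeholder",
    "split_placeholders_in_dump",
    "check_balance",
    "strip_water_protons",
    "reaction_key",
    "ReactionKey",
    "BalanceReport",
    "identify_small_species",
    "PLACEHOLDER_TOKENS",
    "SMALL_SPECIES_NAMES",
]

# ----------------------------------------------------------- equation text

_ARROW_RE = re.compile(r"\s(<=>|<->|=>|->|→|=)\s")
_TERM_RE = re.compile(r"^(\d+|n)\s+(.+)$")


def parse_equation(
    text: str, source: str, name_to_id: dict[str, str]
) -> tuple[tuple[Participant, ...], tuple[Participant, ...], str]:
    """Parse equation text into (left, right, direction).

    Exactly one arrow token (``<=>``, ``=>``, ``->``, ``→``, ``=``)
    must be present; participants are split on `` + ``; a leading
    integer (or the symbol ``n``) is the coefficient, default 1.
    Participant names resolve against the source's preferred names and
    synonyms (exact, then case-folded).  Unresolvable names raise.
    """
    arrows = _ARROW_RE.findall(text)
    if len(arrows) != 1:
        raise ValueError(
            f"expected exactly one reaction arrow, found {len(arrows)}: {text!r}"
        )
    lhs, arrow, rhs = _ARROW_RE.split(text)
    direction = ARROW_DIRECTIONS[arrow]

    def parse_side(side_text: str) -> tuple[Participant, ...]:
        out = []
        for term in side_text.split(" + "):
            term = term.strip()
            if not term:
                raise ValueError(f"empty participant in {text!r}")
            m = _TERM_RE.match(term)
            if m:
                coeff = m.group(1) if m.group(1) == "n" else int(m.group(1))
                name = m.group(2)
            else:
                coeff, name = 1, term
            cid = name_to_id.get(name) or name_to_id.get(name.casefold())
            if cid is None:
                raise ValueError(f"unresolvable participant name {name!r}")
            out.append((coeff, (source, cid)))
        return tuple(out)

    return parse_side(lhs), parse_side(rhs), direction


# -------------------------------------------------- NAD(P)(H) placeholders

#: placeholder spellings (uppercased, spaces removed) -> redox state
PLACEHOLDER_TOKENS: dict[str, str] = {
    "NAD(P)+": "oxidized",
    "NAD(P)H": "reduced",
    "NADP-OR-NOP": "oxidized",
    "NAD-P-OR-NOP": "oxidized",
    "NADPH_OR_NO_P": "reduced",
    "NADPH-OR-NOPH": "reduced",
}

_SUBSTITUTES = {
    ("oxidized", "with_p"): "NADP+",
    ("reduced", "with_p"): "NADPH",
    ("oxidized", "wop"): "NAD+",
    ("reduced", "wop"): "NADH",
}


def _placeholder_state(compound: CompoundRecord,
                       tokens: dict[str, str]) -> str | None:
    for n in compound.all_names():
        state = tokens.get(n.upper().replace(" ", ""))
        if state:
            return state
    return None


def split_nadp_placeholder(
    r: ReactionRecord,
    compounds: dict[str, CompoundRecord],
    tokens: dict[str, str] | None = None,
) -> tuple[list[ReactionRecord], list[CompoundRecord]]:
    """Split a phosphate-ambiguous nicotinamide-cofactor reaction in two.

    A reaction written with NAD(P)+/NAD(P)H stands for two reactions;
    it is emitted once with NADP+/NADPH under the original ID and once
    with NAD+/NADH under the ID suffixed ``_WOP`` (without phosphate).
    Substitute compound records are looked up by name in the source's
    compound table; missing ones are synthesised (structureless) and
    returned so the caller can extend the table.  A placeholder without
    its redox partner anywhere in the reaction is malformed: the
    reaction passes through unchanged with a warning.
    """
    tokens = tokens if tokens is not None else PLACEHOLDER_TOKENS
    states: dict[Ref, str] = {}
    for coeff, ref in r.participants():
        c = compounds.get(ref[1])
        if c is None:
            continue
        state = _placeholder_state(c, tokens)
        if state:
            states[ref] = state
    if not states:
        return [r], []
    if len(set(states.values())) < 2:
        log.warning(
            "%s:%s: cofactor placeholder without redox partner; not split",
            r.source, r.reaction_id,
        )
        return [r], []

    by_name = {}
    for c in compounds.values():
        for n in c.all_names():
            by_name.setdefault(n.upper(), c)
    new_compounds: list[CompoundRecord] = []

    def substitute_ref(name: str) -> Ref:
        c = by_name.get(name.upper())
        if c is None:
            c = CompoundRecord(source=r.source, compound_id=f"__{name}__",
                               name=name)
            by_name[name.upper()] = c
            new_compounds.append(c)
        return c.ref

    def build(variant: str, rid: str) -> ReactionRecord:
        def sub_side(side):
            return tuple(
                (coeff, substitute_ref(_SUBSTITUTES[(states[ref], variant)]))
                if ref in states else (coeff, ref)
                for coeff, ref in side
            )

        return replace(r, reaction_id=rid, left=sub_side(r.left),
                       right=sub_side(r.right))

    return (
        [build("with_p", r.reaction_id),
         build("wop", r.reaction_id + "_WOP")],
        new_compounds,
    )


def split_placeholders_in_dump(
    dump: SourceDump, tokens: dict[str, str] | None = None
) -> SourceDump:
    """Apply :func:`split_nadp_placeholder` to every reaction of a dump."""
    table = dump.compound_by_id()
    reactions: list[ReactionRecord] = []
    added: list[CompoundRecord] = []
    for r in dump.reactions:
        split, new_compounds = split_nadp_placeholder(r, table, tokens)
        reactions.extend(split)
        for c in new_compounds:
            table[c.compound_id] = c
            added.append(c)
    return SourceDump(label=dump.label, compounds=dump.compounds + added,
                      reactions=reactions, aliases=dict(dump.aliases),
                      issues=list(dump.issues))


# ------------------------------------------------------------ balance QC

@dataclass(frozen=True)
class BalanceReport:
    """Outcome of the element-balance check on one reaction."""

    status: str  # balanced | balanced_tolerated | incomplete | undetermined
    deficit_left: ElementCounts | None = None   # atoms missing on substrate side
    deficit_right: ElementCounts | None = None  # atoms missing on product side
    tolerated_species: frozenset[str] = frozenset()

    @property
    def missing_substrate(self) -> str:
        return counts_to_formula(self.deficit_left.counts) if self.deficit_left else ""

    @property
    def missing_product(self) -> str:
        return counts_to_formula(self.deficit_right.counts) if self.deficit_right else ""


def check_balance(
    r: ReactionRecord,
    class_of: dict[Ref, int],
    formulas: dict[int, ElementCounts | None],
) -> BalanceReport:
    """Element-balance a reaction against class-level formulas.

    Run before water/proton stripping.  Formulas are the neutral-parent
    InChI formula layers, so protonation differences surface as H-count
    differences and fall under the proton tolerance.
    """
    totals = []
    for side in (r.left, r.right):
        acc: dict[str, int] = {}
        for coeff, ref in side:
            if coeff == "n":
                return BalanceReport(status="undetermined")
            cls = class_of.get(ref)
            ec = formulas.get(cls) if cls is not None else None
            if ec is None or ec.has_unknown:
                return BalanceReport(status="undetermined")
            for el, n in ec.counts.items():
                acc[el] = acc.get(el, 0) + coeff * n
        totals.append(acc)
    left, right = totals
    diff = {el: left.get(el, 0) - right.get(el, 0)
            for el in set(left) | set(right)}
    diff = {el: d for el, d in diff.items() if d != 0}
    if not diff:
        return BalanceReport(status="balanced")

    # tolerate a*H + b*H2O missing from exactly one side
    if set(diff) <= {"H", "O"} and (
        all(d > 0 for d in diff.values()) or all(d < 0 for d in diff.values())
    ):
        sign = 1 if next(iter(diff.values())) > 0 else -1
        h = abs(diff.get("H", 0))
        b = abs(diff.get("O", 0))
        a = h - 2 * b
        if a >= 0:
            species = frozenset(
                (["proton"] if a else []) + (["water"] if b else [])
            )
            deficit = ElementCounts(counts={k: abs(v) for k, v in diff.items()})
            # left heavier => atoms missing on the product side
            if sign > 0:
                return BalanceReport(status="balanced_tolerated",
                                     deficit_right=deficit,
                                     tolerated_species=species)
            return BalanceReport(status="balanced_tolerated",
                                 deficit_left=deficit,
                                 tolerated_species=species)

    missing_right = {el: d for el, d in diff.items() if d > 0}
    missing_left = {el: -d for el, d in diff.items() if d < 0}
    return BalanceReport(
        status="incomplete",
        deficit_left=ElementCounts(counts=missing_left) if missing_left else None,
        deficit_right=ElementCounts(counts=missing_right) if missing_right else None,
    )


# --------------------------------------------------- water/proton removal

#: normalized-name fallbacks recognising water and the proton, for dumps
#: without structures (the proton's own InChI has no formula layer)
SMALL_SPECIES_NAMES: dict[str, str] = {
    "h2o": "water", "water": "water",
    "h+": "proton", "proton": "proton", "hydron": "proton",
}


def identify_small_species(classes, compounds_by_ref) -> dict[int, str]:
    """Map class id -> 'water' | 'proton', by reduced key or normalized name."""
    out: dict[int, str] = {}
    for cls in classes:
        if cls.representative_key is not None and cls.representative_key.key == WATER_KEY:
            out[cls.class_id] = "water"
            continue
        for ref in sorted(cls.members):
            c = compounds_by_ref.get(ref)
            if c is None:
                continue
            kind = next(
                (SMALL_SPECIES_NAMES[normalize_name(n)] for n in c.all_names()
                 if normalize_name(n) in SMALL_SPECIES_NAMES), None)
            if kind:
                out[cls.class_id] = kind
                break
    return out


def strip_water_protons(
    r: ReactionRecord, small_species: set[int], class_of: dict[Ref, int]
) -> ReactionRecord | None:
    """Remove water/proton participants from both sides.

    Returns ``None`` (reaction excluded from matching, logged) when a
    side would become empty.
    """
    def strip(side):
        return tuple(p for p in side if class_of.get(p[1]) not in small_species)

    left, right = strip(r.left), strip(r.right)
    if left == r.left and right == r.right:
        return r
    if not left or not right:
        log.warning("%s:%s: side empty after water/proton removal; excluded",
                    r.source, r.reaction_id)
        return None
    return replace(r, left=left, right=right)


# -------------------------------------------------------------- reaction key

Side = tuple[tuple[int, str], ...]


@dataclass(frozen=True)
class ReactionKey:
    """Direction-agnostic identity of a reaction.

    Each side is the sorted multiset of (compound class id, coefficient
    as text); the lexicographically smaller side is ``side_a`` so a
    reaction and its reverse writing produce the same key.
    """

    side_a: Side
    side_b: Side


def reaction_key(r: ReactionRecord, class_of: dict[Ref, int]) -> ReactionKey | None:
    """Compute the reaction's key; ``None`` if a participant has no class."""
    sides = []
    for side in (r.left, r.right):
        items = []
        for coeff, ref in side:
            cls = class_of.get(ref)
            if cls is None:
                log.warning("%s:%s: participant %s has no compound class",
                            r.source, r.reaction_id, ref)
                return None
            items.append((cls, str(coeff)))
        sides.append(tuple(sorted(items)))
    a, b = sorted(sides)
    return ReactionKey(side_a=a, side_b=b)
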