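"""Collapse equivalent reactions, attach metadata, compute overlap stats.

All reactions sharing a direction-agnostic key become one unique
*merged reaction* carrying: its per-source member IDs (including
``_WOP`` IDs created by the cofactor split), the union of member EC
numbers (a reaction catalysed by several enzymes keeps them all), the
union of pathway annotations, a representative equation rendered with
the stereo-preferred compound names, and a consolidated balance
status.  Overlap statistics count unique reactions per source-subset
(Venn cells) and the number of (EC, reaction) combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import io_model
from .compound_match import CompoundClass, MatchOptions, apply_aliases, match_compounds
from .chem_norm import ElementCounts, formula_to_counts
from .io_model import ReactionRecord, Ref, SourceDump
from .reaction_pipeline import (
    BalanceReport,
    ReactionKey,
    check_balance,
    identify_small_species,
    reaction_key,
    split_placeholders_in_dump,
    strip_water_protons,
)

log = logging.getLogger(__name__)

__all__ = [
    "MergedReaction",
    "OverlapStats",
    "IntegrationResult",
    "merge_reactions",
    "overlap_stats",
    "ec_reaction_combinations",
    "render_equation",
    "run_integration",
]

_STATUS_RANK = {"balanced": 0, "balanced_tolerated": 1, "undetermined": 2,
                "incomplete": 3}


@dataclass
class MergedReaction:
    """One unique reaction of the integrated set."""

    unified_id: str
    key: ReactionKey | None
    members: dict[str, list[str]]            # source -> reaction ids
    member_records: list[ReactionRecord]
    ec_set: frozenset[str]
    pathways: frozenset[tuple[str, str]]
    balance_status: str
    missing_substrate: str = ""
    missing_product: str = ""
    representative_equation: str = ""
    unmatched: bool = False                  # keyless singleton

    def member_rids(self) -> set[tuple[str, str]]:
        return {(s, rid) for s, rids in self.members.items() for rid in rids}


@dataclass
class OverlapStats:
    """Unique-reaction counts per non-empty source subset (Venn cells)."""

    cells: dict[frozenset[str], int]
    per_source: dict[str, int]
    unique_reaction_count: int
    ec_reaction_combination_count: int

    def __post_init__(self):
        total = sum(self.cells.values())
        if total != self.unique_reaction_count:
            raise AssertionError(
                f"Venn cells sum to {total}, expected {self.unique_reaction_count}"
            )
        for src, n in self.per_source.items():
            expect = sum(v for cell, v in self.cells.items() if src in cell)
            if n != expect:
                raise AssertionError(
                    f"per-source total mismatch for {src}: {n} != {expect}"
                )


def _merge_balance(reports: list[BalanceReport]) -> BalanceReport:
    """Consolidated status: the best-documented member wins, but any
    incomplete member downgrades the group (conservative QC — modelers
    filtering for balanced reactions must not pick up a broken form)."""
    if any(rep.status == "incomplete" for rep in reports):
        return next(rep for rep in reports if rep.status == "incomplete")
    return min(reports, key=lambda rep: _STATUS_RANK[rep.status])


def merge_reactions(
    records: list[tuple[ReactionRecord, ReactionKey | None, BalanceReport]],
) -> list[MergedReaction]:
    """One MergedReaction per distinct key; keyless records stay singletons."""
    by_key: dict[ReactionKey, list] = {}
    keyless: list[tuple[ReactionRecord, BalanceReport]] = []
    for rec, key, report in records:
        if key is None:
            keyless.append((rec, report))
        else:
            by_key.setdefault(key, []).append((rec, report))

    merged: list[MergedReaction] = []
    groups = sorted(by_key.items(), key=lambda kv: (kv[0].side_a, kv[0].side_b))
    width = max(6, len(str(len(groups) + len(keyless))))
    for key, group in groups:
        members: dict[str, list[str]] = {}
        for rec, _ in group:
            members.setdefault(rec.source, []).append(rec.reaction_id)
        for rids in members.values():
            rids.sort()
        report = _merge_balance([rep for _, rep in group])
        merged.append(MergedReaction(
            unified_id=f"UR{len(merged) + 1:0{width}d}",
            key=key,
            members=members,
            member_records=[rec for rec, _ in group],
            ec_set=frozenset(ec for rec, _ in group for ec in rec.ec_numbers),
            pathways=frozenset(p for rec, _ in group for p in rec.pathways),
            balance_status=report.status,
            missing_substrate=report.missing_substrate,
            missing_product=report.missing_product,
        ))
    for rec, report in sorted(keyless, key=lambda t: t[0].rid):
        merged.append(MergedReaction(
            unified_id=f"UR{len(merged) + 1:0{width}d}",
            key=None,
            members={rec.source: [rec.reaction_id]},
            member_records=[rec],
            ec_set=frozenset(rec.ec_numbers),
            pathways=frozenset(rec.pathways),
            balance_status=report.status,
            missing_substrate=report.missing_substrate,
            missing_product=report.missing_product,
            unmatched=True,
        ))
    return merged


def ec_reaction_combinations(merged: list[MergedReaction]) -> int:
    """Number of (reaction, EC) pairs; an EC-less reaction counts once."""
    return sum(max(1, len(m.ec_set)) for m in merged)


def overlap_stats(merged: list[MergedReaction]) -> OverlapStats:
    cells: dict[frozenset[str], int] = {}
    per_source: dict[str, int] = {}
    for m in merged:
        cell = frozenset(m.members)
        cells[cell] = cells.get(cell, 0) + 1
        for src in cell:
            per_source[src] = per_source.get(src, 0) + 1
    return OverlapStats(
        cells=cells,
        per_source=per_source,
        unique_reaction_count=len(merged),
        ec_reaction_combination_count=ec_reaction_combinations(merged),
    )


def render_equation(m: MergedReaction, classes: list[CompoundClass]) -> str:
    """Equation text with stereo-preferred representative names,
    coefficient 1 omitted, sides in canonical key order."""
    if m.key is None:
        return ""
    by_id = {c.class_id: c for c in classes}

    def render_side(side):
        return " + ".join(
            by_id[cls].representative_name if coeff == "1"
            else f"{coeff} {by_id[cls].representative_name}"
            for cls, coeff in side
        )

    return f"{render_side(m.key.side_a)} <=> {render_side(m.key.side_b)}"


@dataclass
class IntegrationResult:
    """Everything the integration run produced."""

    dumps: list[SourceDump]                  # preprocessed dumps
    classes: list[CompoundClass]
    class_of: dict[Ref, int]
    merged: list[MergedReaction]
    stats: OverlapStats
    balance_reports: dict[tuple[str, str], BalanceReport]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def write_tables(self, out_dir):
        return io_model.write_output_tables(self.merged, self.classes, out_dir)


def class_formulas(
    classes: list[CompoundClass],
) -> dict[int, ElementCounts | None]:
    """Neutral-parent element counts per class, from the representative
    reduced key's formula layer; ``None`` where the class has no structure."""
    out: dict[int, ElementCounts | None] = {}
    for cls in classes:
        if cls.representative_key is None:
            out[cls.class_id] = None
        else:
            out[cls.class_id] = formula_to_counts(
                cls.representative_key.key.split("/")[0]
            )
    return out


def run_integration(
    dumps: list[SourceDump], options: MatchOptions | None = None
) -> IntegrationResult:
    """Full reconciliation pipeline over two or more source dumps."""
    options = options or MatchOptions()
    dumps = [split_placeholders_in_dump(apply_aliases(d)) for d in dumps]

    classes = match_compounds(dumps, options)
    class_of: dict[Ref, int] = {
        ref: cls.class_id for cls in classes for ref in cls.members
    }
    formulas = class_formulas(classes)
    compounds_by_ref = {c.ref: c for d in dumps for c in d.compounds}
    small = identify_small_species(classes, compounds_by_ref)
    for cid, kind in small.items():
        # water/proton composition is known even without a structure
        # record (the bare proton's InChI has no formula layer at all)
        if formulas.get(cid) is None:
            formulas[cid] = ElementCounts(
                counts={"H": 1} if kind == "proton" else {"H": 2, "O": 1})
    small_ids = set(small)

    records = []
    balance_reports: dict[tuple[str, str], BalanceReport] = {}
    excluded: list[tuple[str, str]] = []
    for dump in dumps:
        for r in dump.reactions:
            report = check_balance(r, class_of, formulas)  # pre-strip, always
            balance_reports[r.rid] = report
            stripped = strip_water_protons(r, small_ids, class_of)
            if stripped is None:
                excluded.append(r.rid)
                continue
            records.append((stripped, reaction_key(stripped, class_of), report))

    merged = merge_reactions(records)
    for m in merged:
        m.representative_equation = render_equation(m, classes)
    stats = overlap_stats(merged)
    return IntegrationResult(
        dumps=dumps, classes=classes, class_of=class_of, merged=merged,
        stats=stats, balance_reports=balance_reports, excluded=excluded,
    )
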