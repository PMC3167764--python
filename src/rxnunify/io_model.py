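"""Domain types and readers/writers for reaction-database dumps.

A *source dump* is one database's published view: a compound table
(IDs, preferred name, synonyms, optional structure as Molfile and/or
InChI), a reaction table (participants with stoichiometric
coefficients, direction, EC numbers, pathway annotations) and an
optional alias map (e.g. a glycan-ID namespace folded onto the
compound-ID namespace).  Dumps are read from a JSON file or from a
directory of TSV tables; structures may arrive separately as an SDF
of V2000 Molfiles.  The integration result is exported as three CSV
tables: unique reactions, compound classes, and a link table
connecting the two.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Union

log = logging.getLogger(__name__)

__all__ = [
    "Ref",
    "Coefficient",
    "Participant",
    "CompoundRecord",
    "ReactionRecord",
    "SourceDump",
    "DumpFormatError",
    "read_dump",
    "dump_from_obj",
    "write_dump",
    "read_molfiles",
    "write_output_tables",
]

#: (source label, source-local compound id)
Ref = tuple[str, str]
#: positive integer or the symbolic coefficient 'n'
Coefficient = Union[int, str]
#: (coefficient, compound ref)
Participant = tuple[Coefficient, Ref]

Direction = Literal["reversible", "left_to_right", "unspecified"]

#: arrow tokens accepted in equation text, mapped to directions
ARROW_DIRECTIONS: dict[str, Direction] = {
    "<=>": "reversible",
    "<->": "reversible",
    "=>": "left_to_right",
    "->": "left_to_right",
    "→": "left_to_right",  # →
    "=": "unspecified",
}


class DumpFormatError(ValueError):
    """Malformed dump content; message carries file and line context."""


@dataclass(frozen=True)
class CompoundRecord:
    """One compound as published by one source database."""

    source: str
    compound_id: str
    name: str
    synonyms: tuple[str, ...] = ()
    inchi: str | None = None
    molfile: str | None = None
    is_generic: bool = False

    def __post_init__(self):
        if self.inchi is not None and not self.inchi.startswith("InChI="):
            raise ValueError(
                f"{self.source}:{self.compound_id}: inchi must start with 'InChI='"
            )
        if self.is_generic and self.inchi is not None:
            raise ValueError(
                f"{self.source}:{self.compound_id}: generic compounds carry no structure"
            )

    @property
    def ref(self) -> Ref:
        return (self.source, self.compound_id)

    def all_names(self) -> tuple[str, ...]:
        return (self.name, *self.synonyms)


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction as published by one source database.

    EC entries are complete four-field numbers, incomplete numbers with
    trailing '-' fields, or the literal label ``SPONTANEOUS`` for
    uncatalysed reactions.
    """

    source: str
    reaction_id: str
    left: tuple[Participant, ...]
    right: tuple[Participant, ...]
    ec_numbers: tuple[str, ...] = ()
    direction: Direction = "unspecified"
    pathways: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        for coeff, _ in (*self.left, *self.right):
            if isinstance(coeff, int):
                if coeff < 1:
                    raise ValueError(
                        f"{self.source}:{self.reaction_id}: coefficient {coeff} < 1"
                    )
            elif coeff != "n":
                raise ValueError(
                    f"{self.source}:{self.reaction_id}: bad coefficient {coeff!r}"
                )

    @property
    def rid(self) -> tuple[str, str]:
        return (self.source, self.reaction_id)

    def participants(self) -> tuple[Participant, ...]:
        return (*self.left, *self.right)

    def swapped(self) -> "ReactionRecord":
        d = {"left_to_right": "left_to_right", "reversible": "reversible",
             "unspecified": "unspecified"}[self.direction]
        return replace(self, left=self.right, right=self.left, direction=d)


@dataclass
class SourceDump:
    """One database's compounds, reactions and alias map."""

    label: str
    compounds: list[CompoundRecord] = field(default_factory=list)
    reactions: list[ReactionRecord] = field(default_factory=list)
    aliases: dict[str, str] = field(default_factory=dict)
    #: reader warnings (excluded reactions, dangling refs); not part of equality
    issues: list[str] = field(default_factory=list, compare=False)

    def compound_by_id(self) -> dict[str, CompoundRecord]:
        return {c.compound_id: c for c in self.compounds}

    def __eq__(self, other):
        if not isinstance(other, SourceDump):
            return NotImplemented
        return (
            self.label == other.label
            and self.compounds == other.compounds
            and self.reactions == other.reactions
            and self.aliases == other.aliases
        )


# ---------------------------------------------------------------- reading

def _validate_dump(dump: SourceDump) -> SourceDump:
    """Enforce invariants: unique compound ids, resolvable participant refs
    (directly or through the alias map).  Reactions with dangling refs are
    excluded with a logged warning collected into ``dump.issues``."""
    seen: set[str] = set()
    for c in dump.compounds:
        if c.compound_id in seen:
            raise DumpFormatError(
                f"{dump.label}: duplicate compound id {c.compound_id!r}"
            )
        seen.add(c.compound_id)
    known = seen | set(dump.aliases)
    kept = []
    for r in dump.reactions:
        dangling = [
            cid for _, (_, cid) in r.participants() if cid not in known
        ]
        if dangling:
            msg = (
                f"{dump.label}: reaction {r.reaction_id} excluded, "
                f"dangling compound ref(s): {', '.join(sorted(set(dangling)))}"
            )
            log.warning(msg)
            dump.issues.append(msg)
        else:
            kept.append(r)
    dump.reactions = kept
    return dump


def _participants_from_json(raw, source: str) -> tuple[Participant, ...]:
    out = []
    for item in raw:
        coeff, cid = item
        if isinstance(coeff, str) and coeff != "n":
            coeff = int(coeff)
        if isinstance(cid, (list, tuple)):
            out.append((coeff, (cid[0], cid[1])))
        else:
            out.append((coeff, (source, cid)))
    return tuple(out)


def dump_from_obj(obj: dict) -> SourceDump:
    """Build a SourceDump from an already-parsed JSON-style mapping."""
    label = obj["label"]
    compounds = [
        CompoundRecord(
            source=c.get("source", label),
            compound_id=c["compound_id"],
            name=c.get("name", ""),
            synonyms=tuple(c.get("synonyms", ())),
            inchi=c.get("inchi") or None,
            molfile=c.get("molfile") or None,
            is_generic=bool(c.get("is_generic", False)),
        )
        for c in obj.get("compounds", ())
    ]
    dump = SourceDump(label=label, compounds=compounds,
                      aliases=dict(obj.get("aliases", {})))
    by_name = None
    reactions = []
    for i, r in enumerate(obj.get("reactions", ())):
        source = r.get("source", label)
        rid = r["reaction_id"]
        common = dict(
            source=source,
            reaction_id=rid,
            ec_numbers=tuple(r.get("ec_numbers", ())),
            pathways=tuple((p[0], p[1]) for p in r.get("pathways", ())),
        )
        try:
            if "equation" in r and r["equation"]:
                from .reaction_pipeline import parse_equation  # cycle guard

                if by_name is None:
                    by_name = _name_lookup(compounds)
                left, right, direction = parse_equation(
                    r["equation"], source, by_name
                )
                reactions.append(
                    ReactionRecord(left=left, right=right,
                                   direction=direction, **common)
                )
            else:
                reactions.append(
                    ReactionRecord(
                        left=_participants_from_json(r["left"], source),
                        right=_participants_from_json(r["right"], source),
                        direction=r.get("direction", "unspecified"),
                        **common,
                    )
                )
        except (KeyError, ValueError) as exc:
            msg = f"{label}: reaction #{i} ({rid}): {exc}"
            log.warning(msg)
            dump.issues.append(msg)
    dump.reactions = reactions
    return _validate_dump(dump)


def _name_lookup(compounds: Iterable[CompoundRecord]) -> dict[str, str]:
    """Exact and case-folded name/synonym -> compound_id within one source."""
    exact: dict[str, str] = {}
    folded: dict[str, str] = {}
    for c in compounds:
        for n in c.all_names():
            exact.setdefault(n, c.compound_id)
            folded.setdefault(n.casefold(), c.compound_id)
    folded.update(exact)
    return folded


def read_dump(path, format: str = "json", sdf=None) -> SourceDump:
    """Read a source dump.

    ``format='json'``: a single JSON file.  ``format='tsv'``: a
    directory containing ``compounds.tsv``, ``reactions.tsv`` and
    optionally ``aliases.tsv``.  ``sdf``: optional SDF path whose
    Molfiles are attached to compounds via their ``molfile_ref``
    column (TSV) or record ID.

    Malformed rows raise :class:`DumpFormatError` with line context;
    reactions with dangling compound refs are excluded with a warning
    recorded in ``dump.issues``.
    """
    path = Path(path)
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise DumpFormatError(f"{path}: invalid JSON: {exc}") from exc
        dump = dump_from_obj(obj)
    elif format == "tsv":
        dump = _read_tsv_dir(path, sdf=sdf)
    else:
        raise ValueError(f"unknown dump format {format!r}")
    return dump


def _read_tsv_dir(path: Path, sdf=None) -> SourceDump:
    molmap = read_molfiles(sdf) if sdf else {}
    compounds: list[CompoundRecord] = []
    label = None
    cfile = path / "compounds.tsv"
    with open(cfile, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                label = label or row["source"]
                molref = row.get("molfile_ref", "") or ""
                compounds.append(
                    CompoundRecord(
                        source=row["source"],
                        compound_id=row["compound_id"],
                        name=row["name"],
                        synonyms=tuple(
                            s for s in (row.get("synonyms") or "").split("|") if s
                        ),
                        inchi=row.get("inchi") or None,
                        molfile=molmap.get(molref) if molref else None,
                        is_generic=(row.get("is_generic", "") or "").lower()
                        in ("1", "true", "yes"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise DumpFormatError(f"{cfile}:{lineno}: {exc}") from exc
    dump = SourceDump(label=label or path.name, compounds=compounds)
    afile = path / "aliases.tsv"
    if afile.exists():
        with open(afile, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for lineno, row in enumerate(reader, start=2):
                try:
                    dump.aliases[row["alias_id"]] = row["canonical_id"]
                except KeyError as exc:
                    raise DumpFormatError(f"{afile}:{lineno}: {exc}") from exc
    rfile = path / "reactions.tsv"
    by_name = _name_lookup(compounds)
    from .reaction_pipeline import parse_equation

    with open(rfile, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                source = row["source"]
                rid = row["reaction_id"]
            except KeyError as exc:
                raise DumpFormatError(f"{rfile}:{lineno}: {exc}") from exc
            try:
                left, right, direction = parse_equation(
                    row["equation"], source, by_name
                )
                dump.reactions.append(
                    ReactionRecord(
                        source=source,
                        reaction_id=rid,
                        left=left,
                        right=right,
                        direction=direction,
                        ec_numbers=tuple(
                            e for e in (row.get("ec_numbers") or "").split(";") if e
                        ),
                        pathways=tuple(
                            tuple(p.split(":", 1)) if ":" in p else ("", p)
                            for p in (row.get("pathways") or "").split(";")
                            if p
                        ),
                    )
                )
            except ValueError as exc:
                msg = f"{rfile}:{lineno}: reaction {rid}: {exc}"
                log.warning(msg)
                dump.issues.append(msg)
    return _validate_dump(dump)


# ---------------------------------------------------------------- writing

def _participant_to_json(p: Participant, source: str):
    coeff, (src, cid) = p
    return [coeff, cid if src == source else [src, cid]]


def write_dump(dump: SourceDump, path, format: str = "json") -> None:
    """Write a dump so that :func:`read_dump` round-trips it exactly
    (JSON carries structured participants; TSV renders equation text
    from preferred names)."""
    path = Path(path)
    if format == "json":
        obj = {
            "label": dump.label,
            "compounds": [
                {
                    "source": c.source,
                    "compound_id": c.compound_id,
                    "name": c.name,
                    "synonyms": list(c.synonyms),
                    "inchi": c.inchi,
                    "molfile": c.molfile,
                    "is_generic": c.is_generic,
                }
                for c in dump.compounds
            ],
            "reactions": [
                {
                    "source": r.source,
                    "reaction_id": r.reaction_id,
                    "left": [_participant_to_json(p, r.source) for p in r.left],
                    "right": [_participant_to_json(p, r.source) for p in r.right],
                    "direction": r.direction,
                    "ec_numbers": list(r.ec_numbers),
                    "pathways": [list(p) for p in r.pathways],
                }
                for r in dump.reactions
            ],
            "aliases": dump.aliases,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True, ensure_ascii=False)
            fh.write("\n")
    elif format == "tsv":
        _write_tsv_dir(dump, path)
    else:
        raise ValueError(f"unknown dump format {format!r}")


def _write_tsv_dir(dump: SourceDump, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    by_id = dump.compound_by_id()

    def render_side(side):
        terms = []
        for coeff, (_, cid) in side:
            name = by_id[cid].name if cid in by_id else cid
            terms.append(name if coeff == 1 else f"{coeff} {name}")
        return " + ".join(terms)

    arrow = {"reversible": "<=>", "left_to_right": "=>", "unspecified": "="}
    with open(path / "compounds.tsv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "compound_id", "name", "synonyms", "inchi",
                    "molfile_ref", "is_generic"])
        for c in dump.compounds:
            w.writerow([c.source, c.compound_id, c.name, "|".join(c.synonyms),
                        c.inchi or "", "", "true" if c.is_generic else ""])
    with open(path / "reactions.tsv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["source", "reaction_id", "ec_numbers", "equation",
                    "pathways"])
        for r in dump.reactions:
            eq = f"{render_side(r.left)} {arrow[r.direction]} {render_side(r.right)}"
            w.writerow([
                r.source, r.reaction_id, ";".join(r.ec_numbers), eq,
                ";".join(f"{p[0]}:{p[1]}" if p[0] else p[1] for p in r.pathways),
            ])
    if dump.aliases:
        with open(path / "aliases.tsv", "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["source", "alias_id", "canonical_id"])
            for alias, canonical in sorted(dump.aliases.items()):
                w.writerow([dump.label, alias, canonical])


# ------------------------------------------------------------------- SDF

def read_molfiles(path, id_field: str = "ID") -> dict[str, str]:
    """Read an SDF into a map compound_id -> raw Molfile text.

    Records are split on ``$$$$``; the Molfile is everything up to and
    including ``M  END``; the ID is taken from the ``> <ID>`` data
    field (configurable).  Records without the ID field are skipped
    with a warning; a record with no ``M  END`` terminator raises,
    naming the record index.
    """
    text = Path(path).read_text(encoding="utf-8")
    out: dict[str, str] = {}
    records = [r for r in text.split("$$$$") if r.strip()]
    for idx, rec in enumerate(records):
        lines = rec.lstrip("\n").splitlines()
        try:
            end = next(i for i, ln in enumerate(lines) if ln.strip() == "M  END")
        except StopIteration:
            raise DumpFormatError(
                f"{path}: SDF record {idx} truncated (no 'M  END')"
            ) from None
        molfile = "\n".join(lines[: end + 1]) + "\n"
        rec_id = None
        for i, ln in enumerate(lines[end + 1:], start=end + 1):
            if ln.startswith(">") and f"<{id_field}>" in ln:
                if i + 1 < len(lines):
                    rec_id = lines[i + 1].strip()
                break
        if not rec_id:
            log.warning("%s: SDF record %d has no <%s> field, skipped",
                        path, idx, id_field)
            continue
        out[rec_id] = molfile
    return out


# -------------------------------------------------------- output tables

def write_output_tables(merged, classes, out_dir) -> dict[str, Path]:
    """Export the integration result as three CSV tables.

    ``Reactions.csv``: one row per unique reaction — unified ID,
    per-source member IDs, union EC set, representative equation,
    stoichiometry status with Missing Substrate / Missing Product
    deficits, pathways.  ``Compounds.csv``: one row per compound class.
    ``Links.csv``: (unified reaction ID, compound class ID, side,
    coefficient) — one row per participant, connecting the two.
    RFC 4180, UTF-8, header row.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sources = sorted(
        {src for m in merged for src in m.members}
        | {ref[0] for c in classes for ref in c.members}
    )
    paths = {}

    paths["reactions"] = out_dir / "Reactions.csv"
    with open(paths["reactions"], "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["unified_id"]
            + [f"members_{s}" for s in sources]
            + ["ec_numbers", "equation", "stoichiometry",
               "missing_substrate", "missing_product", "pathways"]
        )
        for m in merged:
            w.writerow(
                [m.unified_id]
                + [";".join(m.members.get(s, ())) for s in sources]
                + [
                    ";".join(sorted(m.ec_set)),
                    m.representative_equation,
                    m.balance_status,
                    m.missing_substrate,
                    m.missing_product,
                    ";".join(sorted(f"{p[0]}:{p[1]}" for p in m.pathways)),
                ]
            )

    paths["compounds"] = out_dir / "Compounds.csv"
    with open(paths["compounds"], "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class_id", "name"] + [f"members_{s}" for s in sources]
                   + ["reduced_key", "stereo_relaxed"])
        for c in classes:
            per_source: dict[str, list[str]] = {}
            for src, cid in sorted(c.members):
                per_source.setdefault(src, []).append(cid)
            w.writerow(
                [c.class_id, c.representative_name]
                + [";".join(per_source.get(s, ())) for s in sources]
                + [c.representative_key.key if c.representative_key else "",
                   "yes" if c.has_relaxed_edge else ""]
            )

    paths["links"] = out_dir / "Links.csv"
    with open(paths["links"], "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unified_id", "class_id", "side", "coefficient"])
        for m in merged:
            for side_name, side in (("substrate", m.key.side_a),
                                    ("product", m.key.side_b)):
                for class_id, coeff in side:
                    w.writerow([m.unified_id, class_id, side_name, coeff])
    return paths
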