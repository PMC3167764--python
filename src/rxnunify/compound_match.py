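"""Cross-source compound equivalence classes.

Matching is structure-first: compounds whose reduced (ionisation-
invariant) InChI keys are equal are the same compound, whatever they
are called — identical synonyms can denote different compounds, so
name evidence never overrides structure evidence.  Names are the
fallback where structures are missing (generic compounds, macromolecular
reactants).  An optional relaxed tier merges a compound whose
stereocentres are entirely undefined with the uniquely matching
fully-specified form, because databases mix stereo-free Molfiles with
defined ones (glucose's anomeric centre is the classic case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from networkx.utils import UnionFind

from . import chem_norm
from .io_model import CompoundRecord, Ref, SourceDump
from .name_norm import build_name_index

log = logging.getLogger(__name__)

__all__ = [
    "MatchOptions",
    "CompoundClass",
    "match_compounds",
    "select_representative",
    "apply_aliases",
    "compute_reduced_keys",
]


@dataclass(frozen=True)
class MatchOptions:
    """Knobs for the matcher.

    stereo_relaxed: allow undefined-stereo <-> defined-stereo merges
        (tier 3); such classes are flagged for audit.
    name_matching: allow tier-2 name merges (disabling leaves
        structure-only matching; mainly for ablation studies).
    kept_layers: InChI layers retained in the reduced key.
    """

    stereo_relaxed: bool = True
    name_matching: bool = True
    kept_layers: tuple[str, ...] = chem_norm.DEFAULT_KEPT_LAYERS
    implicit_stereo: dict | None = None


@dataclass
class CompoundClass:
    """A cross-source equivalence class of compounds."""

    class_id: int
    members: frozenset[Ref]
    #: merging edges with the evidence tier that created them
    edges: tuple[tuple[Ref, Ref, str], ...] = ()
    representative: Ref | None = None
    representative_key: chem_norm.ReducedStructureKey | None = None
    representative_name: str = ""

    @property
    def has_relaxed_edge(self) -> bool:
        return any(t == "stereo_relaxed" for _, _, t in self.edges)


def compute_reduced_keys(
    compounds: list[CompoundRecord],
    kept_layers: tuple[str, ...] = chem_norm.DEFAULT_KEPT_LAYERS,
) -> dict[Ref, chem_norm.ReducedStructureKey]:
    """Reduced key per structure-bearing compound.

    Compounds whose InChI fails to parse (e.g. the bare proton, whose
    identifier has no formula layer) are treated as structureless and
    logged.
    """
    keys: dict[Ref, chem_norm.ReducedStructureKey] = {}
    for c in compounds:
        if c.inchi is None:
            continue
        try:
            keys[c.ref] = chem_norm.reduced_key_from_inchi(c.inchi, kept_layers)
        except chem_norm.InChIError as exc:
            log.warning("compound %s:%s treated as structureless: %s",
                        c.source, c.compound_id, exc)
    return keys


def match_compounds(
    dumps: list[SourceDump], options: MatchOptions | None = None
) -> list[CompoundClass]:
    """Partition all compounds of all dumps into equivalence classes.

    Union-find over three edge generators, applied in order:

    1. equal reduced structure key;
    2. equal normalized name where at least one endpoint has no
       structure — refused (and logged) when it would bridge two
       structure-bearing classes with different keys;
    3. (if ``options.stereo_relaxed``) equal stereo-stripped key where
       one endpoint's key carries no stereo layers at all and exactly
       one fully-defined counterpart key exists.

    Class ids are deterministic: ordinal over the classes sorted by
    their lexicographically smallest member.
    """
    options = options or MatchOptions()
    compounds = [c for d in dumps for c in d.compounds]
    refs = [c.ref for c in compounds]
    by_ref = {c.ref: c for c in compounds}
    keys = compute_reduced_keys(compounds, options.kept_layers)

    uf = UnionFind(refs)
    edges: list[tuple[Ref, Ref, str]] = []

    # tier 1: identical reduced structure key
    by_key: dict[str, list[Ref]] = {}
    for ref in refs:
        if ref in keys:
            by_key.setdefault(keys[ref].key, []).append(ref)
    for group in by_key.values():
        group.sort()
        for other in group[1:]:
            uf.union(group[0], other)
            edges.append((group[0], other, "structure"))

    # a root's structure key (unique after tier 1), for the tier-2 guard
    _root_keys: dict[Ref, str] = {}
    for ref, k in keys.items():
        _root_keys[uf[ref]] = k.key

    def union_guarded(a: Ref, b: Ref, tier: str) -> bool:
        ra, rb = uf[a], uf[b]
        if ra == rb:
            return True
        ka, kb = _root_keys.get(ra), _root_keys.get(rb)
        if ka is not None and kb is not None and ka != kb:
            log.warning(
                "name-match conflict: refusing to merge %s and %s "
                "(distinct structures %s / %s)", a, b, ka, kb
            )
            return False
        uf.union(a, b)
        root = uf[a]
        _root_keys[root] = ka if ka is not None else kb
        edges.append((a, b, tier))
        return True

    # tier 2: equal normalized name, at least one endpoint structureless
    if options.name_matching:
        index = build_name_index(compounds, options.implicit_stereo)
        for name_key, group in sorted(index.entries.items()):
            group = sorted(group)
            structureless = [r for r in group if r not in keys]
            structured = [r for r in group if r in keys]
            if not structureless:
                continue
            anchor = structureless[0]
            for other in structureless[1:]:
                union_guarded(anchor, other, "name")
            for other in structured:
                union_guarded(anchor, other, "name")

    # tier 3: undefined stereo joined to the unique fully-defined form
    if options.stereo_relaxed:
        by_stripped: dict[str, list[Ref]] = {}
        for ref, k in keys.items():
            by_stripped.setdefault(k.stereo_stripped_key, []).append(ref)
        for stripped, group in sorted(by_stripped.items()):
            undefined = sorted(r for r in group if not keys[r].has_stereo)
            defined_keys = sorted({keys[r].key for r in group if keys[r].has_stereo})
            if not undefined or not defined_keys:
                continue
            if len(defined_keys) > 1:
                log.warning(
                    "stereo-relaxed merge skipped for %s: %d distinct "
                    "defined-stereo forms", stripped, len(defined_keys)
                )
                continue
            target = min(r for r in group if keys[r].key == defined_keys[0])
            for ref in undefined:
                ra, rb = uf[ref], uf[target]
                if ra != rb:
                    uf.union(ref, target)
                    edges.append((ref, target, "stereo_relaxed"))
                    _root_keys[uf[ref]] = defined_keys[0]

    # assemble classes
    groups: dict[Ref, list[Ref]] = {}
    for ref in refs:
        groups.setdefault(uf[ref], []).append(ref)
    edge_by_root: dict[Ref, list] = {}
    for a, b, tier in edges:
        edge_by_root.setdefault(uf[a], []).append((a, b, tier))
    classes = []
    for members in sorted(groups.values(), key=lambda ms: min(ms)):
        root = uf[members[0]]
        cls = CompoundClass(
            class_id=len(classes),
            members=frozenset(members),
            edges=tuple(edge_by_root.get(root, ())),
        )
        rep = select_representative(cls, keys)
        classes.append(replace(
            cls,
            representative=rep,
            representative_key=keys.get(rep),
            representative_name=by_ref[rep].name,
        ))
    return classes


def select_representative(
    cls: CompoundClass, keys: dict[Ref, chem_norm.ReducedStructureKey]
) -> Ref:
    """Member with the most complete stereochemistry.

    Structure-bearing members outrank structureless ones; among keys,
    more defined stereo descriptors win; ties break lexicographically
    on (source, compound_id) for determinism.
    """
    def rank(ref: Ref):
        k = keys.get(ref)
        return (
            0 if k is not None else 1,
            -(k.stereo_descriptor_count() if k is not None else 0),
            ref,
        )

    return min(cls.members, key=rank)


def apply_aliases(dump: SourceDump) -> SourceDump:
    """Rewrite aliased participant refs to canonical compound IDs.

    Alias chains are resolved transitively; cycles raise.  Compound
    records published under an alias ID are absorbed: their names are
    appended to the canonical record's synonyms and the alias record
    is dropped.
    """
    if not dump.aliases:
        return dump

    resolved: dict[str, str] = {}

    def resolve(cid: str) -> str:
        seen = []
        cur = cid
        while cur in dump.aliases:
            if cur in resolved:
                cur = resolved[cur]
                break
            if cur in seen:
                raise ValueError(f"{dump.label}: alias cycle through {cur!r}")
            seen.append(cur)
            cur = dump.aliases[cur]
        for s in seen:
            resolved[s] = cur
        return cur

    for alias in dump.aliases:
        resolve(alias)

    by_id = dump.compound_by_id()
    absorbed_synonyms: dict[str, list[str]] = {}
    compounds = []
    for c in dump.compounds:
        if c.compound_id in resolved:
            target = resolved[c.compound_id]
            absorbed_synonyms.setdefault(target, []).extend(c.all_names())
            if target not in by_id:
                raise ValueError(
                    f"{dump.label}: alias target {target!r} has no compound record"
                )
        else:
            compounds.append(c)
    compounds = [
        replace(
            c,
            synonyms=c.synonyms + tuple(
                n for n in absorbed_synonyms.get(c.compound_id, ())
                if n and n not in c.all_names()
            ),
        )
        if c.compound_id in absorbed_synonyms else c
        for c in compounds
    ]

    def rewrite(side):
        return tuple(
            (coeff, (src, resolved.get(cid, cid))) for coeff, (src, cid) in side
        )

    reactions = [
        replace(r, left=rewrite(r.left), right=rewrite(r.right))
        for r in dump.reactions
    ]
    return SourceDump(label=dump.label, compounds=compounds,
                      reactions=reactions, aliases={}, issues=list(dump.issues))
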