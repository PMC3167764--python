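"""Compound-name normalization and the synonym index.

Equivalent compound names differ across databases mostly in
punctuation, capitalisation and typography — hyphens, parentheses,
commas, spacing, Greek glyphs vs spelled-out Greek words.  The
normal form keeps only lowercase letters, digits, ``+`` (charged
cofactors such as NAD+) and the apostrophe (primes in nucleotide
names, e.g. 5'-phosphate); everything else is deleted.  Matching is
exact on the normal form — no fuzzy similarity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .io_model import CompoundRecord, Ref

__all__ = [
    "normalize_name",
    "expand_implicit_stereo",
    "build_name_index",
    "NameIndex",
    "DEFAULT_IMPLICIT_STEREO",
]

log = logging.getLogger(__name__)

#: single-glyph Greek letters transliterated to their spelled-out names
#: before the deletion pass, so "β-D-glucose" meets "beta-D-glucose".
GREEK_TRANSLITERATION = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau",
    "υ": "upsilon", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}

_KEEP = re.compile(r"[^a-z0-9+']+")


def normalize_name(name: str, greek_transliteration: bool = True) -> str:
    """Normal form of a compound name.

    Case-folded; Greek glyphs transliterated; every character outside
    ``[a-z0-9+']`` deleted.  Idempotent.  An empty result marks the
    name unusable for matching.
    """
    s = name.casefold()
    if greek_transliteration:
        s = "".join(GREEK_TRANSLITERATION.get(ch, ch) for ch in s)
    return _KEEP.sub("", s)


# The 19 chiral standard amino acids: a bare name implicitly denotes the
# L-form in biochemical usage, so the qualified synonym is added.
DEFAULT_IMPLICIT_STEREO: dict[str, str] = {
    name: f"L-{name}"
    for name in (
        "alanine", "arginine", "asparagine", "aspartate", "cysteine",
        "glutamate", "glutamine", "histidine", "isoleucine", "leucine",
        "lysine", "methionine", "phenylalanine", "proline", "serine",
        "threonine", "tryptophan", "tyrosine", "valine",
    )
}


def expand_implicit_stereo(
    name: str, table: dict[str, str] | None = None
) -> list[str]:
    """Return the name plus any descriptor-qualified expansion.

    Used only to enrich synonym lists — never to overwrite structure
    evidence.  The lookup is on the normal form of the bare name.
    """
    if table is None:
        table = DEFAULT_IMPLICIT_STEREO
    norm_table = {normalize_name(k): v for k, v in table.items()}
    out = [name]
    qualified = norm_table.get(normalize_name(name))
    if qualified is not None:
        out.append(qualified)
    return out


@dataclass
class NameIndex:
    """Map from normalized name to the compound refs carrying it."""

    entries: dict[str, set[Ref]] = field(default_factory=dict)
    #: provenance of each (normalized name, ref) pair:
    #: {"preferred", "synonym", "systematic"}
    provenance: dict[tuple[str, Ref], set[str]] = field(default_factory=dict)
    unusable: list[Ref] = field(default_factory=list)

    def add(self, name: str, ref: Ref, kind: str) -> None:
        key = normalize_name(name)
        if not key:
            return
        self.entries.setdefault(key, set()).add(ref)
        self.provenance.setdefault((key, ref), set()).add(kind)


def build_name_index(
    compounds: list[CompoundRecord],
    implicit_stereo: dict[str, str] | None = None,
) -> NameIndex:
    """Index every preferred name, synonym and implicit-stereo expansion.

    Compounds whose names all normalize to the empty string are logged
    and excluded from name-based matching.
    """
    index = NameIndex()
    for c in compounds:
        ref = (c.source, c.compound_id)
        usable = False
        names = [(c.name, "preferred")] + [(s, "synonym") for s in c.synonyms]
        for raw, kind in names:
            if not raw:
                continue
            for expanded in expand_implicit_stereo(raw, implicit_stereo):
                key = normalize_name(expanded)
                if key:
                    usable = True
                    index.add(expanded, ref, kind if expanded == raw else "systematic")
        if not usable:
            index.unusable.append(ref)
            log.warning("compound %s:%s has no usable name", c.source, c.compound_id)
    return index
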