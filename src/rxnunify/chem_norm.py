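"""Ionisation-invariant structure keys from InChI strings.

An InChI is a layered, canonical linear descriptor: a version prefix,
a Hill-order formula layer, then optional layers introduced by ``/``
and a lowercase letter — connectivity (``c``), hydrogens (``h``),
charge (``q``), protonation (``p``), double-bond and tetrahedral
stereochemistry (``b``, ``t``, ``m``, ``s``), isotopes (``i``).

For cross-database compound matching the ionisation-dependent layers
are noise: a database may deposit acetic acid where another deposits
acetate.  Dropping ``/q`` and ``/p`` (and ``/i``) from the identifier
yields a *reduced structure key* under which all protonation states of
one parent structure compare equal.  A further *stereo-stripped* form
(formula + ``c`` + ``h`` only) supports relaxed matching of compounds
whose stereocentres one database left undefined.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field

__all__ = [
    "InChIError",
    "CapabilityError",
    "InChILayers",
    "ReducedStructureKey",
    "ElementCounts",
    "parse_inchi",
    "reduce_inchi",
    "strip_stereo",
    "formula_to_counts",
    "molfile_to_inchi",
    "reduced_key_from_inchi",
    "DEFAULT_KEPT_LAYERS",
    "WATER_KEY",
]

#: layers retained in the reduced key; /q, /p (ionisation) and /i
#: (isotopes) are dropped.  Overridable per call.
DEFAULT_KEPT_LAYERS: tuple[str, ...] = ("c", "h", "b", "t", "m", "s")

#: canonical ordering of the single-letter layers within an InChI
_LAYER_ORDER = "chqpbtmsi"

_STEREO_LAYERS = frozenset("btms")


class InChIError(ValueError):
    """Raised for structurally invalid InChI input."""


class CapabilityError(RuntimeError):
    """An optional external capability (structure converter) is absent."""


@dataclass(frozen=True)
class InChILayers:
    """Lossless decomposition of an InChI string."""

    prefix: str                       # e.g. "1S"
    formula: str                      # Hill formula layer, '.'-separated components
    layers: tuple[tuple[str, str], ...]  # (letter, payload) in original order

    def layer(self, letter: str) -> str | None:
        for k, v in self.layers:
            if k == letter:
                return v
        return None

    def unparse(self) -> str:
        parts = [f"InChI={self.prefix}", self.formula]
        parts.extend(k + v for k, v in self.layers)
        return "/".join(parts)


@dataclass(frozen=True)
class ReducedStructureKey:
    """Ionisation-invariant structure key plus its stereo-stripped form."""

    key: str
    stereo_stripped_key: str

    @property
    def has_stereo(self) -> bool:
        return self.key != self.stereo_stripped_key

    def stereo_descriptor_count(self) -> int:
        """Number of *defined* stereo descriptors ('?' entries excluded)."""
        n = 0
        for seg in self.key.split("/")[1:]:
            if seg and seg[0] in ("b", "t"):
                n += sum(1 for tok in seg[1:].split(",") if tok and not tok.endswith("?"))
        return n


@dataclass
class ElementCounts:
    """Total element counts of a formula; degenerate inputs set has_unknown."""

    counts: dict[str, int] = field(default_factory=dict)
    has_unknown: bool = False

    def __bool__(self) -> bool:  # usable for balance arithmetic?
        return not self.has_unknown


def parse_inchi(inchi: str) -> InChILayers:
    """Decompose an InChI string losslessly into its layers.

    Raises :class:`InChIError` when the ``InChI=`` prefix is missing or
    the formula layer is empty (e.g. the bare-proton identifier).
    """
    if not isinstance(inchi, str) or not inchi.startswith("InChI="):
        raise InChIError(f"missing 'InChI=' prefix: {inchi!r}")
    body = inchi[len("InChI="):]
    parts = body.split("/")
    if len(parts) < 2:
        raise InChIError(f"no formula layer: {inchi!r}")
    prefix = parts[0]
    formula = parts[1]
    # the formula layer starts with an element symbol or a component
    # multiplier; a lowercase first character means it is already a
    # letter-coded layer, i.e. the formula layer is absent.
    if not formula or not (formula[0].isupper() or formula[0].isdigit()):
        raise InChIError(f"empty formula layer: {inchi!r}")
    layers = []
    for seg in parts[2:]:
        if not seg or not seg[0].islower():
            raise InChIError(f"malformed layer segment {seg!r} in {inchi!r}")
        layers.append((seg[0], seg[1:]))
    return InChILayers(prefix=prefix, formula=formula, layers=tuple(layers))


def _expand_components(formula: str) -> list[str]:
    """Split a formula layer on '.' and expand leading multipliers."""
    out: list[str] = []
    for comp in formula.split("."):
        m = re.match(r"^(\d+)(.*)$", comp)
        if m and m.group(2):
            out.extend([m.group(2)] * int(m.group(1)))
        else:
            out.append(comp)
    return out


def _expand_payload(payload: str) -> list[str]:
    """Split a per-component layer payload on ';' expanding 'k*' repeats."""
    out: list[str] = []
    for tok in payload.split(";"):
        m = re.match(r"^(\d+)\*(.*)$", tok)
        if m:
            out.extend([m.group(2)] * int(m.group(1)))
        else:
            out.append(tok)
    return out


def _sorted_components(formula: str, kept: list[tuple[str, str]]):
    """Component-sort formula plus c/h payloads so salt keys are
    order-invariant.  Applied only when every kept layer is c/h and the
    payloads split cleanly into one entry per component; otherwise the
    original order is preserved (standard InChI already canonicalises
    component order, so this path is defensive)."""
    comps = _expand_components(formula)
    if len(comps) <= 1:
        return formula, kept
    if any(k not in ("c", "h") for k, _ in kept):
        return formula, kept
    per_layer = {}
    for k, v in kept:
        expanded = _expand_payload(v)
        if len(expanded) != len(comps):
            return formula, kept
        per_layer[k] = expanded
    rows = sorted(
        (comps[i], per_layer.get("c", [""] * len(comps))[i], per_layer.get("h", [""] * len(comps))[i])
        for i in range(len(comps))
    )
    new_formula = ".".join(r[0] for r in rows)
    new_kept = []
    for k, _ in kept:
        idx = 1 if k == "c" else 2
        new_kept.append((k, ";".join(r[idx] for r in rows)))
    return new_formula, new_kept


def reduce_inchi(
    layers: InChILayers, kept_layers: tuple[str, ...] = DEFAULT_KEPT_LAYERS
) -> ReducedStructureKey:
    """Drop the version prefix and the ionisation/isotope layers.

    The key is the formula layer plus the kept layers, joined with '/'
    in canonical InChI layer order.
    """
    kept = [(k, v) for k, v in layers.layers if k in kept_layers]
    kept.sort(key=lambda kv: _LAYER_ORDER.index(kv[0]) if kv[0] in _LAYER_ORDER else 99)
    formula, kept = _sorted_components(layers.formula, kept)
    key = "/".join([formula] + [k + v for k, v in kept])
    stripped = "/".join(
        [formula] + [k + v for k, v in kept if k not in _STEREO_LAYERS]
    )
    return ReducedStructureKey(key=key, stereo_stripped_key=stripped)


def strip_stereo(key: ReducedStructureKey) -> str:
    """Stereo-free form of a reduced key: formula + c + h layers only."""
    return key.stereo_stripped_key


def reduced_key_from_inchi(
    inchi: str, kept_layers: tuple[str, ...] = DEFAULT_KEPT_LAYERS
) -> ReducedStructureKey:
    """Convenience composition of :func:`parse_inchi` and :func:`reduce_inchi`."""
    return reduce_inchi(parse_inchi(inchi), kept_layers)


#: reduced key of water, used for small-species recognition
WATER_KEY = "H2O/h1H2"

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_to_counts(formula_layer: str) -> ElementCounts:
    """Total element counts over all '.'-separated formula components.

    Leading integer multipliers apply to their component.  Repeating
    units, '*'-placeholders or anything unparsable set ``has_unknown``
    and empty the counts.
    """
    counts: dict[str, int] = {}
    for comp in formula_layer.split("."):
        m = re.match(r"^(\d*)(.*)$", comp)
        mult = int(m.group(1)) if m.group(1) else 1
        body = m.group(2)
        if not body:
            return ElementCounts(has_unknown=True)
        pos = 0
        for em in _ELEMENT_RE.finditer(body):
            if em.start() != pos:
                return ElementCounts(has_unknown=True)
            pos = em.end()
            n = int(em.group(2)) if em.group(2) else 1
            counts[em.group(1)] = counts.get(em.group(1), 0) + mult * n
        if pos != len(body):
            return ElementCounts(has_unknown=True)
    return ElementCounts(counts=counts)


def counts_to_formula(counts: dict[str, int]) -> str:
    """Render element counts as a Hill-order formula string."""
    if not counts:
        return ""
    keys = sorted(counts)
    if "C" in counts:
        keys = ["C"] + (["H"] if "H" in counts else []) + [
            k for k in keys if k not in ("C", "H")
        ]
    return "".join(f"{k}{counts[k] if counts[k] != 1 else ''}" for k in keys if counts[k])


def molfile_to_inchi(molfile: str) -> str:
    """Convert a V2000 Molfile to a standard InChI.

    Uses RDKit's embedded official InChI library when importable; an
    ``inchi-1``-style external converter found on PATH is a fallback.
    Raises :class:`CapabilityError` when no converter is available —
    the pipeline then runs on supplied InChI strings only.
    """
    if not molfile or not molfile.strip():
        raise ValueError("empty Molfile")
    try:
        from rdkit import Chem
        from rdkit.Chem.inchi import MolToInchi
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.*")
        mol = Chem.MolFromMolBlock(molfile)
        if mol is None:
            raise ValueError("unparsable Molfile")
        inchi = MolToInchi(mol)
        if not inchi:
            raise ValueError("InChI generation failed for Molfile")
        return inchi
    except ImportError:
        pass
    exe = shutil.which("inchi-1")
    if exe is None:
        raise CapabilityError(
            "no Molfile->InChI converter available (rdkit not importable, "
            "inchi-1 not on PATH); supply InChI strings directly"
        )
    proc = subprocess.run(
        [exe, "-STDIO", "-AuxNone", "-NoLabels"],
        input=molfile, capture_output=True, text=True,
    )
    for line in proc.stdout.splitlines():
        if line.startswith("InChI="):
            return line.strip()
    raise ValueError("external converter produced no InChI")
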