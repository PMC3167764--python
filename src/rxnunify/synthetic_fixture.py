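"""Synthetic multi-source dumps with known ground truth.

The generator builds a pool of surrogate metabolites — small CHNO
molecules with valid layered InChI strings and element-exact formulas —
and a set of element-balanced base reactions over them (condensations,
hydrations, nicotinamide-cofactor redox pairs, and optionally reactions
over generic name-only compounds).  Each of ``n_sources`` databases
then publishes its own copy of the pool and the reactions, perturbed by
exactly the obstacles real reaction databases present:

* synonym renaming and punctuation/case/Greek-glyph noise in names;
* protonation variants of a structure (extra ``/p`` layer);
* structures republished with all stereocentres undefined;
* water or a proton written on one side of an equation;
* reversed equations; duplicated records within one source;
* a glycan-style alias ID namespace for some compounds;
* NAD(P)(H) placeholder reactions standing for an NAD and an NADP form;
* dropped structures (name-only records);
* deliberate element-balance corruption with a known atom deficit.

Every perturbation records its truth label, so recovery of compound
classes, reaction classes and balance statuses can be scored exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, fields

from .chem_norm import counts_to_formula
from .io_model import CompoundRecord, ReactionRecord, Ref, SourceDump

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "RecoveryMetrics",
    "generate_fixture",
    "score_recovery",
    "score_integration",
]

RId = tuple[str, str]  # (source, reaction_id)


@dataclass(frozen=True)
class FixtureSpec:
    """Generation conditions; the seed fully determines the output."""

    n_base_compounds: int = 28
    n_base_reactions: int = 18
    n_sources: int = 3
    seed: int = 0
    # perturbation rates, each the probability per applicable site
    synonym_rename: float = 0.3
    case_hyphen_noise: float = 0.5
    protonation_variant: float = 0.3
    stereo_undefined_variant: float = 0.3
    add_water: float = 0.2
    add_proton: float = 0.2
    reverse_direction: float = 0.3
    within_source_duplicate: float = 0.15
    glycan_alias: float = 0.2
    nadp_placeholder_collapse: float = 0.5
    drop_structure: float = 0.2
    corrupt_balance: float = 0.2
    #: fraction of base reactions over generic name-only compounds
    generic_fraction: float = 0.1
    #: deliberate cross-compound synonym collision (exercises the
    #: name-match guard); off by default
    name_collision: bool = False

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not 0.0 <= v <= 1.0:
                raise ValueError(f"rate {f.name}={v} outside [0, 1]")
        if self.n_base_compounds < 8 or self.n_base_reactions < 1 or self.n_sources < 1:
            raise ValueError("fixture too small to generate non-empty dumps")


@dataclass
class GroundTruth:
    """True labels recorded by the generative process."""

    #: (source, compound_id) -> base-compound label
    compound_class: dict[Ref, str] = field(default_factory=dict)
    #: (source, reaction_id) -> base-reaction label (post-split IDs)
    reaction_class: dict[RId, str] = field(default_factory=dict)
    #: (source, reaction_id) -> (status, missing_substrate, missing_product)
    expected_balance: dict[RId, tuple[str, str, str]] = field(default_factory=dict)


# ------------------------------------------------------- surrogate chemistry

_GREEK = ("alpha", "beta", "gamma", "delta", "omega")


class _Metabolite:
    """A base metabolite: exact formula, surrogate InChI, name pool."""

    def __init__(self, label: str, idx: int, counts: dict[str, int],
                 stereo_centres: int = 0, generic: bool = False):
        self.label = label
        self.idx = idx
        self.counts = counts if not generic else None
        self.generic = generic
        if generic or counts is None:
            self.inchi = None
            self.names = [label]  # e.g. "an aldehyde", or a name-only species
            return
        heavy = sum(n for el, n in counts.items() if el != "H")
        formula = counts_to_formula(counts)
        layers = ""
        if heavy >= 2:
            layers += "/c" + "-".join(str(i) for i in range(1, heavy + 1))
        layers += f"/h{min(2, heavy)}-{heavy}H" if heavy > 2 else "/h1H2"
        if stereo_centres:
            t = ",".join(f"{i + 2}{'-' if i % 2 else '+'}"
                         for i in range(stereo_centres))
            layers += f"/t{t}/m1/s1"
        self.inchi = f"InChI=1S/{formula}{layers}"
        g = _GREEK[idx % len(_GREEK)]
        self.names = [
            f"{g}-D-metabolite-{idx}",
            f"{g} metabolite {idx}",
            f"metabolite-{idx} ({g} form)",
        ]


def _strip_stereo_layers(inchi: str) -> str:
    return "/".join(
        seg for seg in inchi.split("/") if not (seg and seg[0] in "btms")
    )


def _noise(name: str, rng: random.Random) -> str:
    """Surface noise that leaves the normalized form unchanged."""
    out = name
    if rng.random() < 0.5:
        out = out.replace("-", " ", 1)
    if rng.random() < 0.5:
        out = out.replace("alpha", "α").replace("beta", "β")
    if rng.random() < 0.5:
        out = "".join(ch.upper() if rng.random() < 0.3 else ch for ch in out)
    if rng.random() < 0.3:
        out = out.replace(" ", ", ", 1)
    return out


# cofactor surrogates: real molecular formulas, fabricated layers; the
# reduced/oxidised pair differs by H2 so redox reactions balance without
# explicit protons
_COFACTORS = {
    "NAD+": {"C": 21, "H": 27, "N": 7, "O": 14, "P": 2},
    "NADH": {"C": 21, "H": 29, "N": 7, "O": 14, "P": 2},
    "NADP+": {"C": 21, "H": 28, "N": 7, "O": 17, "P": 3},
    "NADPH": {"C": 21, "H": 30, "N": 7, "O": 17, "P": 3},
}

_WATER_COUNTS = {"H": 2, "O": 1}


class _Pool:
    """Registry of base metabolites, created on demand per (family, k)."""

    def __init__(self, max_compounds: int):
        self.by_key: dict[tuple[str, int], _Metabolite] = {}
        self.order: list[_Metabolite] = []
        self.max_compounds = max_compounds
        self._next_idx = 0

    def _new(self, key, counts, stereo=0, generic=False, label=None) -> _Metabolite:
        m = _Metabolite(label or f"M{self._next_idx:03d}", self._next_idx,
                        counts, stereo_centres=stereo, generic=generic)
        self._next_idx += 1
        self.by_key[key] = m
        self.order.append(m)
        return m

    def get(self, family: str, k: int) -> _Metabolite:
        key = (family, k)
        if key in self.by_key:
            return self.by_key[key]
        if family == "sugar":      # C_k H_2k O_k, stereo for k >= 3
            return self._new(key, {"C": k, "H": 2 * k, "O": k},
                             stereo=min(k - 1, 3) if k >= 3 else 0)
        if family == "hydrate":    # C_k H_2k+2 O_k+1
            return self._new(key, {"C": k, "H": 2 * k + 2, "O": k + 1})
        if family == "alcohol":    # C_k H_2k+2 O
            return self._new(key, {"C": k, "H": 2 * k + 2, "O": 1})
        if family == "aldehyde":   # C_k H_2k O  (k >= 2: k=1 collides with sugar)
            return self._new(key, {"C": k, "H": 2 * k, "O": 1})
        raise KeyError(family)

    def special(self, name: str, counts=None, generic=False) -> _Metabolite:
        key = ("special", name)
        if ("special", name) in self.by_key:
            return self.by_key[key]
        return self._new(key, counts, generic=generic, label=name)


@dataclass
class _BaseReaction:
    label: str
    left: list[tuple[int, str]]      # (coefficient, metabolite label)
    right: list[tuple[int, str]]
    ec: tuple[str, ...]
    #: for redox pairs emitted as one placeholder record: the label of
    #: the partner NADP-form reaction, plus the placeholder participants
    placeholder_partner: str | None = None


def _signature(left, right):
    a = tuple(sorted((lbl, c) for c, lbl in left))
    b = tuple(sorted((lbl, c) for c, lbl in right))
    return tuple(sorted((a, b)))


# --------------------------------------------------------------- generation

def generate_fixture(spec: FixtureSpec) -> tuple[list[SourceDump], GroundTruth]:
    """Generate ``spec.n_sources`` dumps plus their ground truth.

    Deterministic in ``spec`` (byte-identical dumps for equal specs).
    """
    rng = random.Random(spec.seed)
    pool = _Pool(spec.n_base_compounds)
    k_max = max(4, spec.n_base_compounds // 4)

    water = pool.special("H2O", dict(_WATER_COUNTS))
    water.names = ["H2O", "water"]
    proton = pool.special("H+", None, generic=False)
    proton.counts = {"H": 1}   # known to the truth; no parsable InChI exists
    proton.inchi = None
    proton.names = ["H+", "proton"]
    cofactors = {}
    for name, counts in _COFACTORS.items():
        m = pool.special(name, dict(counts))
        m.names = [name]
        cofactors[name] = m

    if spec.name_collision:
        collide = [pool.get("sugar", 2), pool.get("sugar", 3)]
        for m in collide:
            m.names.append("common impurity")

    # ---- base reactions, balanced by construction
    base: list[_BaseReaction] = []
    seen_sigs: set = set()
    n_generic = round(spec.generic_fraction * spec.n_base_reactions)
    templates = ["condensation", "hydration", "redox"]
    guard = 0
    while len(base) < spec.n_base_reactions and guard < 10000:
        guard += 1
        i = len(base)
        if n_generic > 0:
            kind = "generic"
            n_generic -= 1
        else:
            # rotate over attempts, not successes, so an exhausted
            # template cannot deadlock generation
            kind = templates[(i + guard) % len(templates)]
        if kind == "redox" and len(base) + 2 > spec.n_base_reactions:
            kind = "condensation"   # a redox pair needs two slots
        if kind == "condensation":
            a = rng.randint(2, max(2, k_max // 2))
            b = rng.randint(2, max(2, k_max - a))
            x, y = rng.randint(1, 3), rng.randint(1, 3)
            left = ([(x + y, pool.get("sugar", a).label)] if a == b
                    else [(x, pool.get("sugar", a).label),
                          (y, pool.get("sugar", b).label)])
            product_k = x * a + y * b
            if rng.random() < spec.corrupt_balance:
                product_k -= 1          # one CH2O unit vanishes
            right = [(1, pool.get("sugar", product_k).label)]
            ec = (f"2.4.1.{10 + i}",)
        elif kind == "hydration":
            k = rng.randint(2, k_max)
            x = rng.randint(1, 3)
            left = [(x, pool.get("sugar", k).label), (x, water.label)]
            right = [(x, pool.get("hydrate", k).label)]
            ec = (f"3.2.1.{10 + i}",) if rng.random() < 0.8 else ("SPONTANEOUS",)
        elif kind == "redox":
            k = rng.randint(2, k_max)
            nad = _BaseReaction(
                label=f"RXN{len(base):03d}",
                left=[(1, pool.get("alcohol", k).label), (1, "NAD+")],
                right=[(1, pool.get("aldehyde", k).label), (1, "NADH")],
                ec=(f"1.1.1.{10 + i}",),
            )
            sig = _signature(nad.left, nad.right)
            if sig in seen_sigs or len(base) + 2 > spec.n_base_reactions:
                continue
            seen_sigs.add(sig)
            base.append(nad)
            nadp = _BaseReaction(
                label=f"RXN{len(base):03d}",
                left=[(1, pool.get("alcohol", k).label), (1, "NADP+")],
                right=[(1, pool.get("aldehyde", k).label), (1, "NADPH")],
                ec=(f"1.1.1.{10 + i}",),
            )
            seen_sigs.add(_signature(nadp.left, nadp.right))
            nad.placeholder_partner = nadp.label
            base.append(nadp)
            continue
        else:  # generic
            ox = pool.special("an alcohol", None, generic=True)
            red = pool.special("an aldehyde", None, generic=True)
            cof = ("NAD+", "NADH") if n_generic % 2 == 0 else ("NADP+", "NADPH")
            left = [(1, ox.label), (1, cof[0])]
            right = [(1, red.label), (1, cof[1])]
            ec = ("1.1.1.-",)
        sig = _signature(left, right)
        if sig in seen_sigs:
            continue
        seen_sigs.add(sig)
        base.append(_BaseReaction(label=f"RXN{len(base):03d}", left=left,
                                  right=right, ec=ec))

    if len(base) < spec.n_base_reactions:
        raise ValueError(
            f"could only generate {len(base)} distinct base reactions of the "
            f"{spec.n_base_reactions} requested; enlarge n_base_compounds"
        )
    if not base or not pool.order:
        raise ValueError("specification produced an empty fixture")

    truth = GroundTruth()
    counts_of = {m.label: m.counts for m in pool.order}
    dumps: list[SourceDump] = []

    # pass 1: per-source compound tables (so structure availability
    # across all sources is known before balance labels are assigned)
    per_source: list[dict] = []
    has_structure: set[str] = {"H2O", "H+"}  # composition known regardless
    for s in range(spec.n_sources):
        src = f"DB{s + 1}"
        src_rng = random.Random(rng.randrange(2 ** 31))
        cid_of: dict[str, str] = {}
        compounds: list[CompoundRecord] = []
        aliases: dict[str, str] = {}
        alias_of: dict[str, str] = {}   # metabolite label -> alias id in use

        for m in pool.order:
            cid = f"{src}_C{m.idx:03d}"
            cid_of[m.label] = cid
            names = list(m.names)
            if len(names) > 1 and src_rng.random() < spec.synonym_rename:
                names = names[1:] + names[:1]
            if src_rng.random() < spec.case_hyphen_noise:
                names = [_noise(n, src_rng) for n in names]
            inchi = m.inchi
            if inchi and "/t" in inchi and src_rng.random() < spec.stereo_undefined_variant:
                inchi = _strip_stereo_layers(inchi)
            if inchi and src_rng.random() < spec.protonation_variant:
                inchi = inchi + ("/p-1" if src_rng.random() < 0.5 else "/p+1")
            if inchi and src_rng.random() < spec.drop_structure:
                inchi = None
            if inchi:
                has_structure.add(m.label)
            compounds.append(CompoundRecord(
                source=src, compound_id=cid, name=names[0],
                synonyms=tuple(names[1:]), inchi=inchi,
                is_generic=m.generic,
            ))
            truth.compound_class[(src, cid)] = m.label
            if not m.generic and m.label not in ("H2O", "H+") and \
                    src_rng.random() < spec.glycan_alias:
                gid = f"{src}_G{m.idx:03d}"
                aliases[gid] = cid
                alias_of[m.label] = gid
        per_source.append(dict(src=src, rng=src_rng, cid_of=cid_of,
                               compounds=compounds, aliases=aliases,
                               alias_of=alias_of))

    known_counts = {lbl: c for lbl, c in counts_of.items()
                    if lbl in has_structure}

    # pass 2: per-source reaction tables with truth labels
    for state in per_source:
        src = state["src"]
        src_rng = state["rng"]
        cid_of = state["cid_of"]
        compounds = state["compounds"]
        aliases = state["aliases"]
        alias_of = state["alias_of"]
        placeholder_added = False

        def ref_of(label: str) -> Ref:
            return (src, alias_of.get(label, cid_of[label]))

        reactions: list[ReactionRecord] = []
        j = 0
        while j < len(base):
            br = base[j]
            rid = f"{src}_R{j:03d}"
            collapse = (
                br.placeholder_partner is not None
                and src_rng.random() < spec.nadp_placeholder_collapse
            )
            if collapse and not placeholder_added:
                # a placeholder record names both forms at once; name
                # normalization resolves it to the phosphate form, which
                # is also the form kept under the original id on split
                for pname, resolved in (("NAD(P)+", "NADP+"),
                                        ("NAD(P)H", "NADPH")):
                    pcid = f"{src}_{pname}"
                    compounds.append(CompoundRecord(
                        source=src, compound_id=pcid, name=pname))
                    cid_of[pname] = pcid
                    truth.compound_class[(src, pcid)] = resolved
                placeholder_added = True

            if collapse:
                # one placeholder record stands for the NADP form (kept
                # under the original id on split) and the NAD form (_WOP)
                subs = {"NAD+": "NAD(P)+", "NADH": "NAD(P)H"}
                left = [(c, ref_of(subs.get(l, l))) for c, l in br.left]
                right = [(c, ref_of(subs.get(l, l))) for c, l in br.right]
                outputs = [
                    (rid, base[j + 1].label,
                     {"NAD(P)+": "NADP+", "NAD(P)H": "NADPH"}),
                    (rid + "_WOP", br.label,
                     {"NAD(P)+": "NAD+", "NAD(P)H": "NADH"}),
                ]
                j += 2
            else:
                left = [(c, ref_of(l)) for c, l in br.left]
                right = [(c, ref_of(l)) for c, l in br.right]
                outputs = [(rid, br.label, {})]
                j += 1

            direction = "reversible"
            if src_rng.random() < spec.add_water:
                side = left if src_rng.random() < 0.5 else right
                side.append((1, ref_of("H2O")))
            if src_rng.random() < spec.add_proton:
                side = left if src_rng.random() < 0.5 else right
                side.append((1, ref_of("H+")))
            if src_rng.random() < spec.reverse_direction:
                left, right = right, left
                direction = "left_to_right"

            reactions.append(ReactionRecord(
                source=src, reaction_id=rid, left=tuple(left),
                right=tuple(right), direction=direction, ec_numbers=br.ec,
            ))
            duplicate = src_rng.random() < spec.within_source_duplicate
            if duplicate:
                reactions.append(ReactionRecord(
                    source=src, reaction_id=rid + "b", left=tuple(left),
                    right=tuple(right), direction=direction, ec_numbers=br.ec,
                ))

            cid_to_label = {v: k for k, v in cid_of.items()}
            for out_rid, label, subs in outputs:
                status = _expected_balance(left, right, subs, cid_to_label,
                                           alias_of, known_counts)
                out_ids = [out_rid]
                if duplicate:
                    out_ids.append(out_rid.replace(rid, rid + "b", 1))
                for oid in out_ids:
                    truth.reaction_class[(src, oid)] = label
                    truth.expected_balance[(src, oid)] = status

        dumps.append(SourceDump(label=src, compounds=compounds,
                                reactions=reactions, aliases=aliases))

    return dumps, truth


def _expected_balance(left, right, placeholder_subs, cid_to_label, alias_of,
                      counts_of) -> tuple[str, str, str]:
    """Independent element tally over true formulas (the generator's own
    balance oracle, not the pipeline's)."""
    alias_to_label = {v: k for k, v in alias_of.items()}

    def label_of(ref: Ref) -> str:
        cid = ref[1]
        lbl = cid_to_label.get(cid)
        if lbl is None:  # alias id
            lbl = alias_to_label.get(cid)
        lbl = placeholder_subs.get(lbl, lbl)
        return lbl

    totals = []
    for side in (left, right):
        acc: dict[str, int] = {}
        for coeff, ref in side:
            if coeff == "n":
                return ("undetermined", "", "")
            lbl = label_of(ref)
            counts = counts_of.get(lbl)
            if counts is None:
                return ("undetermined", "", "")
            for el, n in counts.items():
                acc[el] = acc.get(el, 0) + coeff * n
        totals.append(acc)
    l, r = totals
    diff = {el: l.get(el, 0) - r.get(el, 0) for el in set(l) | set(r)}
    diff = {el: d for el, d in diff.items() if d}
    if not diff:
        return ("balanced", "", "")
    if set(diff) <= {"H", "O"} and (all(d > 0 for d in diff.values())
                                    or all(d < 0 for d in diff.values())):
        h = abs(diff.get("H", 0))
        o = abs(diff.get("O", 0))
        if h - 2 * o >= 0:
            formula = counts_to_formula({k: abs(v) for k, v in diff.items()})
            if next(iter(diff.values())) > 0:
                return ("balanced_tolerated", "", formula)
            return ("balanced_tolerated", formula, "")
    missing_right = {el: d for el, d in diff.items() if d > 0}
    missing_left = {el: -d for el, d in diff.items() if d < 0}
    return ("incomplete", counts_to_formula(missing_left),
            counts_to_formula(missing_right))


# ------------------------------------------------------------------ scoring

@dataclass
class RecoveryMetrics:
    compound_precision: float
    compound_recall: float
    compound_f1: float
    reaction_precision: float
    reaction_recall: float
    reaction_f1: float
    #: (expected status, computed status) -> count
    balance_confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def balance_agreement(self) -> float:
        total = sum(self.balance_confusion.values())
        if total == 0:
            return 1.0
        agree = sum(v for (e, c), v in self.balance_confusion.items() if e == c)
        return agree / total


def _pairwise(predicted: list[set], true_label: dict) -> tuple[float, float, float]:
    """Pairwise precision/recall/F1 of predicted co-membership against
    true labels, via the contingency table."""
    pred_label = {}
    for i, members in enumerate(predicted):
        for m in members:
            pred_label[m] = i
    if set(pred_label) != set(true_label):
        raise ValueError("predicted classes and truth cover different entities")

    def npairs(n):
        return n * (n - 1) // 2

    from collections import Counter

    pred_sizes = Counter(pred_label.values())
    true_sizes = Counter(true_label.values())
    cell_sizes = Counter((pred_label[m], true_label[m]) for m in pred_label)
    tp = sum(npairs(n) for n in cell_sizes.values())
    p_pairs = sum(npairs(n) for n in pred_sizes.values())
    t_pairs = sum(npairs(n) for n in true_sizes.values())
    precision = tp / p_pairs if p_pairs else 1.0
    recall = tp / t_pairs if t_pairs else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def score_recovery(
    compound_classes: list[set[Ref]],
    reaction_classes: list[set[RId]],
    truth: GroundTruth,
    computed_balance: dict[RId, tuple[str, str, str]] | None = None,
) -> RecoveryMetrics:
    """Pairwise precision/recall/F1 against the ground truth.

    ``computed_balance`` maps reaction ids to (status, missing substrate
    formula, missing product formula); when given, a confusion matrix of
    expected vs computed status is included (deficit formulas must match
    for a tolerated/incomplete agreement to count).
    """
    cp, cr, cf = _pairwise(compound_classes, truth.compound_class)
    rp, rr, rf = _pairwise(reaction_classes, truth.reaction_class)
    confusion: dict[tuple[str, str], int] = {}
    if computed_balance is not None:
        for rid, expected in truth.expected_balance.items():
            got = computed_balance.get(rid)
            if got is None:
                key = (expected[0], "missing")
            elif got == expected:
                key = (expected[0], expected[0])
            elif got[0] == expected[0]:
                key = (expected[0], f"{got[0]} (deficit mismatch)")
            else:
                key = (expected[0], got[0])
            confusion[key] = confusion.get(key, 0) + 1
    return RecoveryMetrics(
        compound_precision=cp, compound_recall=cr, compound_f1=cf,
        reaction_precision=rp, reaction_recall=rr, reaction_f1=rf,
        balance_confusion=confusion,
    )


def score_integration(result, truth: GroundTruth) -> RecoveryMetrics:
    """Score an :class:`~rxnunify.merge_export.IntegrationResult`."""
    compound_classes = [set(c.members) for c in result.classes]
    reaction_classes = [set(m.member_rids()) for m in result.merged]
    computed = {
        rid: (rep.status, rep.missing_substrate, rep.missing_product)
        for rid, rep in result.balance_reports.items()
    }
    return score_recovery(compound_classes, reaction_classes, truth, computed)
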