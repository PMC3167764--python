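"""Equation parsing, cofactor splitting, balance QC and reaction keys."""

import random

import pytest

from rxnunify.chem_norm import ElementCounts, formula_to_counts
from rxnunify.io_model import CompoundRecord, ReactionRecord
from rxnunify.reaction_pipeline import (
    check_balance,
    parse_equation,
    reaction_key,
    split_nadp_placeholder,
    strip_water_protons,
)

NAMES = {
    "Diphosphate": "c1", "H2O": "c2", "Orthophosphate": "c3",
    "trehalose": "c4", "β-D-glucose": "c5", "H+": "c6",
}


class TestParseEquation:
    def test_reversible_with_coefficient(self):
        left, right, direction = parse_equation(
            "Diphosphate + H2O <=> 2 Orthophosphate", "S", NAMES)
        assert left == ((1, ("S", "c1")), (1, ("S", "c2")))
        assert right == ((2, ("S", "c3")),)
        assert direction == "reversible"

    def test_unicode_arrow_is_directed(self):
        left, right, direction = parse_equation(
            "trehalose + H2O → 2 β-D-glucose", "S", NAMES)
        assert direction == "left_to_right"
        assert right == ((2, ("S", "c5")),)

    def test_symbolic_coefficient(self):
        left, _, _ = parse_equation("n H2O <=> Diphosphate", "S", NAMES)
        assert left == (("n", ("S", "c2")),)

    @pytest.mark.parametrize("bad", [
        "Diphosphate = H2O = Orthophosphate",      # two arrows
        "Diphosphate Orthophosphate",              # none
    ])
    def test_arrow_count_enforced(self, bad):
        with pytest.raises(ValueError, match="arrow"):
            parse_equation(bad, "S", NAMES)

    def test_unresolvable_name(self):
        with pytest.raises(ValueError, match="unresolvable"):
            parse_equation("unobtainium <=> H2O", "S", NAMES)


def _cofactor_table(source="S"):
    records = [
        CompoundRecord(source, "p1", "NAD(P)+"),
        CompoundRecord(source, "p2", "NAD(P)H"),
        CompoundRecord(source, "n1", "NAD+"),
        CompoundRecord(source, "n2", "NADH"),
        CompoundRecord(source, "np1", "NADP+"),
        CompoundRecord(source, "np2", "NADPH"),
        CompoundRecord(source, "a", "an alcohol", is_generic=True),
        CompoundRecord(source, "b", "an aldehyde", is_generic=True),
        CompoundRecord(source, "h", "H+"),
    ]
    return {c.compound_id: c for c in records}


class TestPlaceholderSplit:
    def reaction(self):
        return ReactionRecord(
            source="S", reaction_id="BRX1",
            left=((1, ("S", "a")), (1, ("S", "p1"))),
            right=((1, ("S", "b")), (1, ("S", "p2")), (1, ("S", "h"))),
        )

    def test_split_produces_both_phosphorylation_states(self):
        split, new = split_nadp_placeholder(self.reaction(), _cofactor_table())
        assert [r.reaction_id for r in split] == ["BRX1", "BRX1_WOP"]
        assert new == []
        with_p, wop = split
        assert (1, ("S", "np1")) in with_p.left
        assert (1, ("S", "np2")) in with_p.right
        assert (1, ("S", "n1")) in wop.left
        assert (1, ("S", "n2")) in wop.right
        # untouched participants keep their coefficients and sides
        for r in split:
            assert (1, ("S", "a")) in r.left
            assert (1, ("S", "h")) in r.right

    def test_no_placeholder_is_identity(self):
        r = ReactionRecord("S", "R1", ((1, ("S", "a")),), ((1, ("S", "b")),))
        split, new = split_nadp_placeholder(r, _cofactor_table())
        assert split == [r] and new == []

    def test_missing_redox_partner_passes_through(self):
        r = ReactionRecord("S", "R1", ((1, ("S", "p1")),), ((1, ("S", "b")),))
        split, _ = split_nadp_placeholder(r, _cofactor_table())
        assert split == [r]

    def test_missing_substitutes_are_synthesised(self):
        table = {k: v for k, v in _cofactor_table().items()
                 if k in ("p1", "p2", "a", "b", "h")}
        split, new = split_nadp_placeholder(self.reaction(), table)
        assert len(split) == 2
        assert sorted(c.name for c in new) == ["NAD+", "NADH", "NADP+", "NADPH"]

    @pytest.mark.parametrize("seed", range(5))
    def test_split_conservation(self, seed):
        # 1 -> 2 with a placeholder, 1 -> 1 without
        rng = random.Random(seed)
        table = _cofactor_table()
        total = 0
        n_with = 0
        for i in range(20):
            has_placeholder = rng.random() < 0.5
            if has_placeholder:
                r = self.reaction()
                n_with += 1
            else:
                r = ReactionRecord("S", f"R{i}", ((1, ("S", "a")),),
                                   ((1, ("S", "b")),))
            total += len(split_nadp_placeholder(r, table)[0])
        assert total == (20 - n_with) + 2 * n_with


def _formulas(*specs):
    """class_id -> ElementCounts from formula strings (None = unknown)."""
    return {i: (formula_to_counts(f) if f else None)
            for i, f in enumerate(specs)}


def _reaction(left, right):
    mk = lambda side: tuple((c, ("S", str(cls))) for c, cls in side)
    return ReactionRecord("S", "R", mk(left), mk(right))


def _class_map(n):
    return {("S", str(i)): i for i in range(n)}


class TestCheckBalance:
    # classes: 0=diphosphate, 1=water, 2=phosphate, 3=proton, 4=hexose,
    # 5=pentose, 6=generic (no formula)
    FORMULAS = _formulas("H4O7P2", "H2O", "H3O4P", "H", "C6H12O6",
                        "C5H10O5", None)
    CLASSES = _class_map(7)

    def check(self, left, right):
        return check_balance(_reaction(left, right), self.CLASSES, self.FORMULAS)

    def test_hydrolysis_is_balanced(self):
        # H4P2O7 + H2O vs 2 H3PO4: both sides H6O8P2 by hand tally
        rep = self.check([(1, 0), (1, 1)], [(2, 2)])
        assert rep.status == "balanced"

    def test_extra_proton_is_tolerated_as_missing_substrate(self):
        rep = self.check([(1, 0), (1, 1)], [(2, 2), (1, 3)])
        assert rep.status == "balanced_tolerated"
        assert rep.tolerated_species == {"proton"}
        assert rep.missing_substrate == "H"
        assert rep.missing_product == ""

    def test_missing_water_is_tolerated(self):
        rep = self.check([(1, 0), (1, 1)], [(1, 0)])   # product lost the water
        assert rep.status == "balanced_tolerated"
        assert rep.tolerated_species == {"water"}
        assert rep.missing_product == "H2O"

    def test_carbon_deficit_is_incomplete(self):
        rep = self.check([(1, 4)], [(1, 5)])
        assert rep.status == "incomplete"
        assert rep.missing_product == "CH2O"
        assert rep.missing_substrate == ""

    def test_mixed_side_deficits_are_incomplete(self):
        # O missing on one side, H on the other: not expressible as
        # protons/water lost from a single side
        formulas = _formulas("CH4O2", "CH2O3")
        rep = check_balance(_reaction([(1, 0)], [(1, 1)]), _class_map(2),
                            formulas)
        assert rep.status == "incomplete"
        assert rep.missing_substrate == "O"
        assert rep.missing_product == "H2"

    def test_lone_oxygen_is_not_water(self):
        formulas = _formulas("CH4O2", "CH4O")
        rep = check_balance(_reaction([(1, 0)], [(1, 1)]), _class_map(2),
                            formulas)
        assert rep.status == "incomplete"
        assert rep.missing_product == "O"

    def test_generic_participant_is_undetermined(self):
        assert self.check([(1, 6)], [(1, 4)]).status == "undetermined"

    def test_symbolic_coefficient_is_undetermined(self):
        assert self.check([("n", 4)], [(1, 4)]).status == "undetermined"

    @pytest.mark.parametrize("seed", range(10))
    def test_random_reactions_agree_with_brute_force_tally(self, seed):
        rng = random.Random(seed)
        pool = ["C6H12O6", "H2O", "C2H4O2", "H3O4P", "CH4", "H"]
        formulas = _formulas(*pool)
        classes = _class_map(len(pool))
        left = [(rng.randint(1, 3), rng.randrange(len(pool)))
                for _ in range(rng.randint(1, 3))]
        right = [(rng.randint(1, 3), rng.randrange(len(pool)))
                 for _ in range(rng.randint(1, 3))]
        rep = check_balance(_reaction(left, right), classes, formulas)

        # independent tally
        def total(side):
            acc = {}
            for coeff, cls in side:
                for el, n in formulas[cls].counts.items():
                    acc[el] = acc.get(el, 0) + coeff * n
            return acc

        tl, tr = total(left), total(right)
        if tl == tr:
            assert rep.status == "balanced"
        else:
            assert rep.status in ("balanced_tolerated", "incomplete")
            # deficits, wherever assigned, must reconcile the two sides
            add = {el: formula_to_counts(rep.missing_substrate).counts.get(el, 0)
                   for el in set(tl) | set(tr)}
            back = {el: formula_to_counts(rep.missing_product).counts.get(el, 0)
                    for el in set(tl) | set(tr)}
            for el in set(tl) | set(tr):
                assert tl.get(el, 0) + add.get(el, 0) == \
                    tr.get(el, 0) + back.get(el, 0)


class TestStripAndKey:
    SMALL = {1, 3}  # class ids of water and proton
    CLASSES = _class_map(7)

    def test_water_removed_from_both_sides(self):
        r = _reaction([(1, 0), (1, 1)], [(2, 2), (1, 3)])
        out = strip_water_protons(r, self.SMALL, self.CLASSES)
        assert out.left == ((1, ("S", "0")),)
        assert out.right == ((2, ("S", "2")),)

    def test_untouched_reaction_identical(self):
        r = _reaction([(1, 0)], [(2, 2)])
        assert strip_water_protons(r, self.SMALL, self.CLASSES) is r

    def test_emptied_side_excludes_reaction(self):
        r = _reaction([(1, 1)], [(1, 3), (1, 0)])  # water = proton + X
        assert strip_water_protons(r, self.SMALL, self.CLASSES) is None

    def test_direction_invariance(self):
        r = _reaction([(1, 0), (2, 4)], [(1, 5)])
        assert reaction_key(r, self.CLASSES) == \
            reaction_key(r.swapped(), self.CLASSES)

    def test_coefficients_distinguish(self):
        a = _reaction([(1, 0)], [(2, 4)])
        b = _reaction([(1, 0)], [(3, 4)])
        assert reaction_key(a, self.CLASSES) != reaction_key(b, self.CLASSES)

    def test_unresolved_participant_gives_no_key(self):
        r = _reaction([(1, 99)], [(1, 0)])
        assert reaction_key(r, self.CLASSES) is None

    @pytest.mark.parametrize("seed", range(6))
    def test_water_proton_addition_never_changes_the_key(self, seed):
        rng = random.Random(seed)
        base = _reaction([(1, 0), (1, 4)], [(1, 5), (1, 2)])
        key = reaction_key(
            strip_water_protons(base, self.SMALL, self.CLASSES), self.CLASSES)
        left, right = list(base.left), list(base.right)
        for _ in range(rng.randint(1, 4)):
            side = left if rng.random() < 0.5 else right
            side.append((rng.randint(1, 2), ("S", rng.choice(["1", "3"]))))
        noisy = ReactionRecord("S", "R", tuple(left), tuple(right))
        stripped = strip_water_protons(noisy, self.SMALL, self.CLASSES)
        assert reaction_key(stripped, self.CLASSES) == key
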