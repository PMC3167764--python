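"""Compound equivalence classes: tiers, guards, representatives, aliases."""

import itertools
import random

import pytest

from rxnunify.compound_match import (
    MatchOptions,
    apply_aliases,
    match_compounds,
)
from rxnunify.io_model import CompoundRecord, ReactionRecord, SourceDump

ACETIC_ACID = "InChI=1S/C2H4O2/c1-2(3)4/h1H3,(H,3,4)"
ACETATE = ACETIC_ACID + "/p-1"
GLUCOSE = "InChI=1S/C6H12O6/c7-1-2-3(8)4(9)5(10)6(11)12-2/h2-11H,1H2"
GLUCOSE_BETA = GLUCOSE + "/t2-,3-,4+,5-,6-/m1/s1"
GLUCOSE_ALPHA = GLUCOSE + "/t2-,3-,4+,5-,6+/m1/s1"


def dump(label, compounds, reactions=(), aliases=None):
    return SourceDump(label=label, compounds=list(compounds),
                      reactions=list(reactions), aliases=dict(aliases or {}))


def classes_as_sets(classes):
    return {frozenset(c.members) for c in classes}


class TestStructureTier:
    def test_protonation_states_merge(self):
        dumps = [
            dump("A", [CompoundRecord("A", "c1", "acetic acid", inchi=ACETIC_ACID)]),
            dump("B", [CompoundRecord("B", "x9", "acetate", inchi=ACETATE)]),
        ]
        classes = match_compounds(dumps)
        assert classes_as_sets(classes) == {frozenset({("A", "c1"), ("B", "x9")})}
        assert classes[0].edges[0][2] == "structure"

    def test_structure_beats_conflicting_names(self):
        # same complete structure under wholly different names is one class
        dumps = [
            dump("A", [CompoundRecord("A", "c1", "beta-D-fructofuranose 1,6-bisphosphate",
                                      inchi=GLUCOSE_BETA)]),
            dump("B", [CompoundRecord("B", "c2", "D-fructose-1,6-bisphosphate",
                                      inchi=GLUCOSE_BETA)]),
        ]
        classes = match_compounds(dumps)
        assert len(classes) == 1

    def test_within_source_duplicates_merge(self):
        d = dump("A", [
            CompoundRecord("A", "c1", "enol form", inchi=ACETIC_ACID),
            CompoundRecord("A", "c2", "keto form", inchi=ACETIC_ACID),
        ])
        assert len(match_compounds([d])) == 1


class TestNameTier:
    def test_generic_names_match_exactly(self):
        dumps = [
            dump("A", [CompoundRecord("A", "g1", "an aldehyde", is_generic=True),
                       CompoundRecord("A", "g2", "an alcohol", is_generic=True)]),
            dump("B", [CompoundRecord("B", "g9", "An Aldehyde", is_generic=True)]),
        ]
        classes = match_compounds(dumps)
        assert classes_as_sets(classes) == {
            frozenset({("A", "g1"), ("B", "g9")}),
            frozenset({("A", "g2")}),
        }

    def test_name_never_bridges_distinct_structures(self):
        # a shared synonym between two different structures is refused
        dumps = [
            dump("A", [CompoundRecord("A", "c1", "isomer", inchi=GLUCOSE_ALPHA)]),
            dump("B", [CompoundRecord("B", "c2", "isomer", inchi=ACETIC_ACID)]),
        ]
        classes = match_compounds(dumps)
        assert len(classes) == 2

    def test_structureless_joins_structured_by_name(self):
        dumps = [
            dump("A", [CompoundRecord("A", "c1", "acetate", inchi=ACETATE)]),
            dump("B", [CompoundRecord("B", "c2", "acetate")]),
        ]
        assert len(match_compounds(dumps)) == 1

    def test_name_matching_can_be_disabled(self):
        dumps = [
            dump("A", [CompoundRecord("A", "c1", "acetate")]),
            dump("B", [CompoundRecord("B", "c2", "acetate")]),
        ]
        assert len(match_compounds(dumps, MatchOptions(name_matching=False))) == 2


class TestStereoRelaxedTier:
    def two_dumps(self):
        return [
            dump("A", [CompoundRecord("A", "c1", "D-glucose", inchi=GLUCOSE)]),
            dump("B", [CompoundRecord("B", "c2", "beta-D-glucose",
                                      inchi=GLUCOSE_BETA)]),
        ]

    def test_undefined_merges_with_unique_defined_form(self):
        classes = match_compounds(self.two_dumps())
        assert len(classes) == 1
        assert classes[0].has_relaxed_edge
        # the fully-specified member represents the class
        assert classes[0].representative == ("B", "c2")

    def test_opt_out_keeps_forms_apart(self):
        classes = match_compounds(self.two_dumps(),
                                  MatchOptions(stereo_relaxed=False))
        assert len(classes) == 2

    def test_ambiguous_defined_forms_block_the_merge(self):
        dumps = self.two_dumps() + [
            dump("C", [CompoundRecord("C", "c3", "alpha-D-glucose",
                                      inchi=GLUCOSE_ALPHA)]),
        ]
        classes = match_compounds(dumps)
        # alpha and beta stay distinct; the undefined record joins neither
        assert len(classes) == 3


class TestRepresentative:
    def test_tie_broken_lexicographically(self):
        dumps = [
            dump("A", [CompoundRecord("A", "c2", "x", inchi=ACETIC_ACID)]),
            dump("B", [CompoundRecord("B", "c1", "y", inchi=ACETATE)]),
        ]
        classes = match_compounds(dumps)
        assert classes[0].representative == ("A", "c2")

    def test_singleton(self):
        classes = match_compounds(
            [dump("A", [CompoundRecord("A", "c1", "only one")])])
        assert classes[0].representative == ("A", "c1")


class TestPartitionProperties:
    def make_dumps(self, seed):
        rng = random.Random(seed)
        inchis = [ACETIC_ACID, GLUCOSE, GLUCOSE_BETA, None, None]
        dumps = []
        for label in ("A", "B", "C"):
            compounds = []
            for i in rng.sample(range(5), k=rng.randint(1, 5)):
                compounds.append(CompoundRecord(
                    label, f"c{i}", f"compound {i}", inchi=inchis[i]))
            dumps.append(dump(label, compounds))
        return dumps

    @pytest.mark.parametrize("seed", range(8))
    def test_classes_partition_the_input(self, seed):
        dumps = self.make_dumps(seed)
        classes = match_compounds(dumps)
        all_refs = {c.ref for d in dumps for c in d.compounds}
        seen = [ref for cls in classes for ref in cls.members]
        assert sorted(seen) == sorted(all_refs)       # disjoint and complete
        # tier-1 completeness: no two classes share a reduced key
        keys = [cls.representative_key.key for cls in classes
                if cls.representative_key is not None]
        assert len(keys) == len(set(keys))

    @pytest.mark.parametrize("seed", range(4))
    def test_order_invariance(self, seed):
        dumps = self.make_dumps(seed)
        baseline = None
        for perm in itertools.permutations(dumps):
            grouping = classes_as_sets(match_compounds(list(perm)))
            baseline = baseline or grouping
            assert grouping == baseline

    def test_no_relaxed_edges_means_single_key_per_class(self):
        dumps = self.make_dumps(3)
        for cls in match_compounds(dumps, MatchOptions(stereo_relaxed=False)):
            from rxnunify.compound_match import compute_reduced_keys
            keys = compute_reduced_keys(
                [c for d in dumps for c in d.compounds if c.ref in cls.members])
            assert len({k.key for k in keys.values()}) <= 1


class TestAliases:
    def base_dump(self, aliases, extra=()):
        compounds = [
            CompoundRecord("K", "C01083", "trehalose", inchi=GLUCOSE),
            *extra,
        ]
        reactions = [ReactionRecord(
            source="K", reaction_id="R1",
            left=((1, ("K", "G00293")),), right=((2, ("K", "C01083")),),
        )]
        return dump("K", compounds, reactions, aliases)

    def test_refs_rewritten_and_record_absorbed(self):
        d = self.base_dump(
            {"G00293": "C01083"},
            extra=[CompoundRecord("K", "G00293", "Trehalose (glycan)")],
        )
        out = apply_aliases(d)
        assert out.reactions[0].left == ((1, ("K", "C01083")),)
        assert [c.compound_id for c in out.compounds] == ["C01083"]
        assert "Trehalose (glycan)" in out.compounds[0].synonyms

    def test_empty_alias_map_is_identity(self):
        d = dump("K", [CompoundRecord("K", "c1", "x")],
                 [ReactionRecord("K", "R1", ((1, ("K", "c1")),),
                                 ((1, ("K", "c1")),))])
        assert apply_aliases(d) is d

    def test_chain_resolves_transitively(self):
        d = self.base_dump({"G00293": "MID", "MID": "C01083"})
        out = apply_aliases(d)
        assert out.reactions[0].left == ((1, ("K", "C01083")),)

    def test_cycle_raises(self):
        d = self.base_dump({"G00293": "MID", "MID": "G00293"})
        with pytest.raises(ValueError, match="cycle"):
            apply_aliases(d)
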