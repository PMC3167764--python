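"""A worked three-database example bundled with the package.

Twelve reaction records drawn from the public KEGG, MetaCyc and BRENDA
entries for three well-known reactions, chosen because together they
exercise every reconciliation mechanism: keto-enol tautomer records
duplicated *within* one database, alternative equation writing styles
(arrow dialects, an explicitly written proton), the glycan-ID alias
namespace, and glucose's defined-vs-undefined anomeric stereochemistry.
A correct reconciliation collapses the twelve records into exactly three
unique reactions.

All InChI strings were generated with the official IUPAC InChI
library (via RDKit) from the corresponding structures.
"""

from __future__ import annotations

from .io_model import SourceDump, dump_from_obj

__all__ = ["bundled_example_dumps", "EXPECTED_GROUPS"]

# Standard InChIs (official InChI software output).  Note that the keto
# and enol tautomers of 3-hydroxyquinolin-4(1H)-one / quinoline-3,4-diol
# share one InChI: the mobile-H layer absorbs the tautomerism.
_QUINOLINOL = "InChI=1S/C9H7NO2/c11-8-5-10-7-4-2-1-3-6(7)9(8)12/h1-5,11H,(H,10,12)"
_O2 = "InChI=1S/O2/c1-2"
_CO = "InChI=1S/CO/c1-2"
_FORMYLANTHRANILATE = "InChI=1S/C8H7NO3/c10-5-9-7-4-2-1-3-6(7)8(11)12/h1-5H,(H,9,10)(H,11,12)"
_DIPHOSPHATE = "InChI=1S/H4O7P2/c1-8(2,3)7-9(4,5)6/h(H2,1,2,3)(H2,4,5,6)"
_PHOSPHATE = "InChI=1S/H3O4P/c1-5(2,3)4/h(H3,1,2,3,4)"
_WATER = "InChI=1S/H2O/h1H2"
_TREHALOSE = (
    "InChI=1S/C12H22O11/c13-1-3-5(15)7(17)9(19)11(21-3)23-12-10(20)8(18)6(16)"
    "4(2-14)22-12/h3-20H,1-2H2/t3-,4-,5-,6-,7+,8+,9-,10-,11-,12+/m1/s1"
)
_GLUCOSE_NO_STEREO = "InChI=1S/C6H12O6/c7-1-2-3(8)4(9)5(10)6(11)12-2/h2-11H,1H2"
_GLUCOSE_BETA = _GLUCOSE_NO_STEREO + "/t2-,3-,4+,5-,6-/m1/s1"

#: expected member grouping after reconciliation, for tests and the
#: acceptance script: each set holds (source, reaction_id) pairs.
EXPECTED_GROUPS = [
    frozenset({("KEGG", "R04915"), ("KEGG", "R05719"),
               ("MetaCyc", "1.13.11.47-RXN"), ("BRENDA", "BR22597")}),
    frozenset({("KEGG", "R00004"), ("MetaCyc", "INORGPYROPHOSPHAT-RXN"),
               ("BRENDA", "BR22749")}),
    frozenset({("KEGG", "R00010"), ("KEGG", "R06103"),
               ("MetaCyc", "TREHALA-RXN"), ("BRENDA", "BR15991"),
               ("BRENDA", "BS370856")}),
]


def bundled_example_dumps() -> list[SourceDump]:
    """The twelve example records as three source dumps."""
    kegg = {
        "label": "KEGG",
        "compounds": [
            {"compound_id": "C06343", "name": "Quinoline-3,4-diol",
             "inchi": _QUINOLINOL},
            {"compound_id": "C16721", "name": "3-Hydroxy-1H-quinolin-4-one",
             "inchi": _QUINOLINOL},
            {"compound_id": "C00007", "name": "Oxygen", "synonyms": ["O2"],
             "inchi": _O2},
            {"compound_id": "C00237", "name": "CO",
             "synonyms": ["Carbon monoxide"], "inchi": _CO},
            {"compound_id": "C05653", "name": "Formylanthranilate",
             "inchi": _FORMYLANTHRANILATE},
            {"compound_id": "C00013", "name": "Diphosphate",
             "synonyms": ["Pyrophosphate"], "inchi": _DIPHOSPHATE},
            {"compound_id": "C00001", "name": "H2O", "synonyms": ["Water"],
             "inchi": _WATER},
            {"compound_id": "C00009", "name": "Orthophosphate",
             "synonyms": ["Phosphate"], "inchi": _PHOSPHATE},
            {"compound_id": "C01083", "name": "alpha, alpha-Trehalose",
             "synonyms": ["alpha,alpha-Trehalose"], "inchi": _TREHALOSE},
            {"compound_id": "C00031", "name": "D-Glucose",
             "synonyms": ["Grape sugar"], "inchi": _GLUCOSE_NO_STEREO},
            # the glycan-namespace record for trehalose: no Molfile,
            # folded onto C01083 by the alias map
            {"compound_id": "G00293", "name": "Trehalose"},
        ],
        "aliases": {"G00293": "C01083"},
        "reactions": [
            {"reaction_id": "R04915", "ec_numbers": ["1.13.11.47"],
             "equation": "Quinoline-3,4-diol + Oxygen <=> Formylanthranilate + CO"},
            {"reaction_id": "R05719", "ec_numbers": ["1.13.11.47"],
             "equation": "3-Hydroxy-1H-quinolin-4-one + Oxygen <=> Formylanthranilate + CO"},
            {"reaction_id": "R00004", "ec_numbers": ["3.6.1.1"],
             "equation": "Diphosphate + H2O <=> 2 Orthophosphate"},
            {"reaction_id": "R00010", "ec_numbers": ["3.2.1.28"],
             "equation": "alpha, alpha-Trehalose + H2O <=> 2 D-Glucose",
             "pathways": [["KEGG", "Starch and sucrose metabolism"]]},
            {"reaction_id": "R06103", "ec_numbers": ["3.2.1.28"],
             "equation": "Trehalose + H2O <=> 2 D-Glucose"},
        ],
    }
    metacyc = {
        "label": "MetaCyc",
        "compounds": [
            {"compound_id": "CPD-QUINOLINOL", "name": "3-hydroxy-1H-quinolin-4-one",
             "inchi": _QUINOLINOL},
            {"compound_id": "OXYGEN-MOLECULE", "name": "oxygen", "inchi": _O2},
            {"compound_id": "CARBON-MONOXIDE", "name": "carbon monoxide",
             "inchi": _CO},
            {"compound_id": "CPD-FORMYLANT", "name": "N-formylanthranilate",
             "inchi": _FORMYLANTHRANILATE},
            {"compound_id": "PPI", "name": "diphosphate", "inchi": _DIPHOSPHATE},
            {"compound_id": "WATER", "name": "H2O", "synonyms": ["water"],
             "inchi": _WATER},
            {"compound_id": "Pi", "name": "phosphate", "inchi": _PHOSPHATE},
            # the bare proton's InChI has no formula layer; like the real
            # databases MetaCyc lists it by name only here
            {"compound_id": "PROTON", "name": "H+", "synonyms": ["proton"]},
            {"compound_id": "TREHALOSE", "name": "trehalose",
             "inchi": _TREHALOSE},
            {"compound_id": "GLC", "name": "β-D-glucose", "inchi": _GLUCOSE_BETA},
        ],
        "reactions": [
            {"reaction_id": "1.13.11.47-RXN", "ec_numbers": ["1.13.11.47"],
             "equation": "3-hydroxy-1H-quinolin-4-one + oxygen = carbon monoxide + N-formylanthranilate"},
            {"reaction_id": "INORGPYROPHOSPHAT-RXN", "ec_numbers": ["3.6.1.1"],
             "equation": "diphosphate + H2O = 2 phosphate + H+"},
            {"reaction_id": "TREHALA-RXN", "ec_numbers": ["3.2.1.28"],
             "equation": "trehalose + H2O → 2 β-D-glucose",
             "pathways": [["MetaCyc", "trehalose degradation"]]},
        ],
    }
    brenda = {
        "label": "BRENDA",
        "compounds": [
            {"compound_id": "BC001", "name": "3-hydroxy-1H-quinolin-4-one",
             "inchi": _QUINOLINOL},
            {"compound_id": "BC002", "name": "O2", "synonyms": ["oxygen"],
             "inchi": _O2},
            # stray space as published
            {"compound_id": "BC003", "name": "N- formylanthranilate",
             "synonyms": ["N-formylanthranilate"], "inchi": _FORMYLANTHRANILATE},
            {"compound_id": "BC004", "name": "CO", "inchi": _CO},
            {"compound_id": "BC005", "name": "diphosphate",
             "inchi": _DIPHOSPHATE},
            {"compound_id": "BC006", "name": "H2O", "inchi": _WATER},
            {"compound_id": "BC007", "name": "phosphate", "inchi": _PHOSPHATE},
            {"compound_id": "BC008", "name": "alpha, alpha-trehalose",
             "inchi": _TREHALOSE},
            {"compound_id": "BC009", "name": "D-glucose",
             "inchi": _GLUCOSE_NO_STEREO},
            {"compound_id": "BC010", "name": "beta-Dglucose",
             "inchi": _GLUCOSE_BETA},
        ],
        "reactions": [
            {"reaction_id": "BR22597", "ec_numbers": ["1.13.11.47"],
             "equation": "3-hydroxy-1H-quinolin-4-one + O2 = N- formylanthranilate + CO"},
            {"reaction_id": "BR22749", "ec_numbers": ["3.6.1.1"],
             "equation": "diphosphate + H2O = 2 phosphate"},
            {"reaction_id": "BR15991", "ec_numbers": ["3.2.1.28"],
             "equation": "alpha, alpha-trehalose + H2O = 2 D-glucose"},
            {"reaction_id": "BS370856", "ec_numbers": ["3.2.1.28"],
             "equation": "alpha, alpha-trehalose + H2O = 2 beta-Dglucose"},
        ],
    }
    return [dump_from_obj(kegg), dump_from_obj(metacyc), dump_from_obj(brenda)]
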