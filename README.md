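# rxnunify

Reconcile heterogeneous biochemical reaction databases into a single
non-redundant set of unique reactions, with cross-references back to every
source record.

## The problem

Genome-scale metabolic reconstruction needs the union of the reaction
knowledge scattered over databases such as KEGG, MetaCyc and BRENDA — but
each database publishes the *same* reaction under its own identifiers, its
own compound names, its own equation dialect, and often in several redundant
copies. Equating reactions therefore reduces to equating their participants,
which is anything but trivial: compound names collide ("identical synonyms
may occur for different compounds"), differ only in punctuation or Greek
typography, imply stereochemistry ("alanine" for L-alanine), or are generic
("an aldehyde"); structures are deposited in different protonation states
(acetic acid vs acetate); carbohydrates live in a separate glycan-ID
namespace; phosphate-ambiguous cofactor reactions are written with
NAD(P)(H) placeholders; and many deposited equations are not even
element-balanced.

`rxnunify` implements a structure-first reconciliation engine for this
task, aimed at modelers who need a unified, quality-annotated reaction
table rather than three disagreeing ones.

## Method

**Compound resolution** is a union-find over three evidence tiers, applied
in order:

1. **Structure.** Each InChI is reduced to an ionisation-invariant key:
   the layered identifier `InChI=1S/<formula>/c…/h…/q…/p…/b…/t…/m…/s…/i…`
   is stripped of its version prefix and of the charge (`/q`),
   protonation (`/p`) and isotope (`/i`) layers, keeping
   `formula + /c + /h + /b + /t + /m + /s`. All protonation states of one
   parent structure then compare equal.
2. **Name.** Names are normalized — case-folded, Greek glyphs
   transliterated, every character outside `[a-z0-9+']` deleted — and
   matched exactly. Name evidence is only consulted where a record lacks a
   structure, and never bridges two records whose structure keys disagree.
3. **Stereo-relaxed** (optional, on by default, flagged in the output):
   a record whose stereocentres are entirely undefined joins the unique
   fully-specified form with the same constitution (`formula + /c + /h`),
   e.g. D-glucose with an undefined anomeric centre joins β-D-glucose.
   Classes are represented by the member with the most complete
   stereochemistry.

**Reaction resolution.** After alias application (glycan G-IDs →
compound C-IDs) and splitting of NAD(P)(H)-placeholder reactions into an
NADP form (original ID) and an NAD form (ID + `_WOP`, *without phosphate*),
every reaction is element-balanced against the neutral-parent formulas of
its participant classes: `balanced`, `balanced_tolerated` (the deficit is
a·H + b·H2O on one side), `incomplete` (any other deficit, reported as
Missing Substrate / Missing Product formulas), or `undetermined` (a
participant without formula, or a symbolic coefficient). Only *after* the
balance check are water and protons removed from both sides; each reaction
then becomes a direction-agnostic key — both sides as sorted multisets of
(compound class, coefficient), the sides themselves canonically ordered —
and reactions sharing a key collapse into one unique reaction carrying the
union of member EC numbers and pathway annotations.

## Worked example

The package bundles twelve reaction records drawn from the public KEGG,
MetaCyc and BRENDA entries for three reactions, covering tautomer
duplicates inside one database, an explicitly written proton, the glycan
alias namespace and the glucose anomer problem:

```python
from rxnunify.examples import bundled_example_dumps
from rxnunify import run_integration

result = run_integration(bundled_example_dumps())
for m in result.merged:
    print(m.unified_id, f"[{m.balance_status}]", m.representative_equation,
          "|", ",".join(sorted(m.ec_set)))
```

```
UR000001 [balanced] 3-hydroxy-1H-quinolin-4-one + O2 <=> N- formylanthranilate + CO | 1.13.11.47
UR000002 [balanced] diphosphate <=> 2 phosphate | 3.6.1.1
UR000003 [balanced] alpha, alpha-trehalose <=> 2 beta-Dglucose | 3.2.1.28
```

The twelve records collapse to three unique reactions. `UR000001` unites
four records, including KEGG's keto/enol tautomer pair R04915/R05719;
`UR000002` unites three equation writing styles (the MetaCyc form with its
explicit product-side proton is individually flagged `balanced_tolerated`);
`UR000003` unites five records via the G00293 → C01083 glycan alias and the
stereo-relaxed glucose merge — note the rendered equation uses the
stereo-preferred β-anomer name. Ten compound classes stand behind the three
reactions, water stripped from all of them.

The same pipeline is available from the shell:

```bash
rxnunify simulate --seed 7 --out sim/            # synthetic 3-source corpus
rxnunify merge --dumps sim/DB1.json --dumps sim/DB2.json --dumps sim/DB3.json \
               --out merged/ --stats stats.json
# -> 18 unique reactions, 27 compound classes
```

`merged/` then holds the three-table export — `Reactions.csv` (unique
reactions with per-source member IDs, EC set, stoichiometry status,
Missing Substrate/Product), `Compounds.csv` (compound classes) and
`Links.csv` (reaction ↔ compound incidence) — plus a run manifest.
`rxnunify match-compounds`, `balance` and `score` expose the individual
stages.

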