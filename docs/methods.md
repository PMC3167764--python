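# Methods

This note documents the models and procedures behind `rxnunify`, the
choices that were genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## Reduced structure keys

An InChI is treated as a layered record: version prefix, Hill-order formula
layer, then letter-coded layers in canonical order (`c` connectivity, `h`
hydrogens, `q` charge, `p` protonation, `b/t/m/s` stereochemistry, `i`
isotopes). Parsing is lossless (`InChILayers.unparse()` reproduces the
input byte for byte) and purely syntactic — the package does not
re-implement InChI canonicalization, and assumes standard-form InChIs.
Where only Molfiles are available, `molfile_to_inchi` delegates to RDKit's
embedded copy of the official IUPAC InChI library (or an `inchi-1` binary
on PATH); without a converter the pipeline simply runs on the supplied
InChI strings.

The reduced key keeps `formula + c + h + b + t + m + s`. Dropping `q`
and `p` makes the key invariant under protonation state — the acid and its
conjugate base are one compound for matching purposes. `i` (isotopes) is
also dropped: isotopic labels never distinguish database reactions in
practice. The kept-layer set is a parameter (`MatchOptions.kept_layers`)
for users who disagree.

Multi-component keys (salts): formula components and `c`/`h` payloads are
split per component and sorted jointly so the key is order-invariant.
Stereo layers of multi-component InChIs are kept in input order — standard
InChI already canonicalises component order, so this path is defensive.

Degenerate input: the bare proton's identifier (`InChI=1S/p+1`) has no
formula layer and is rejected by the parser; such records are treated as
structureless and recovered by name (see small species below).

## Name normalization

Names are case-folded, single-glyph Greek letters are transliterated to
their spelled-out forms (`β` → `beta`, preventing `β-D-glucose` vs
`beta-D-glucose` mismatches), and every character outside `[a-z0-9+']` is
deleted. `+` survives for charged cofactors (NAD+), the apostrophe for
primes (5'-phosphate). Digits are kept — positional isomers like
1,6- vs 2,6-bisphosphates must not collapse. Matching is exact on the
normal form; there is deliberately no fuzzy or edit-distance matching.
A shipped table maps the 19 chiral standard amino acids' bare names to
their L-forms as *additional synonyms* (biochemical usage: "alanine"
means L-alanine); the table is replaceable and never overrides structures.

## Compound matching

Union-find over three edge generators, in order:

1. equal reduced key (structure);
2. equal normalized name, where at least one endpoint has no structure —
   guarded so that a name edge never unites two classes carrying
   *different* structure keys (synonym collisions are real; structure
   evidence wins);
3. stereo-relaxed (optional, default on): within a group sharing one
   stereo-stripped key (`formula + c + h`), records with *no* stereo
   layers at all join the defined-stereo form **iff exactly one** defined
   form exists. If both α- and β-forms exist the undefined record joins
   neither (ambiguity is logged). Partially-defined stereo (a `?`
   descriptor in the `t` layer) counts as defined and is not relaxed —
   a known limitation; such records still match by tier 1 or by name.

Class representatives maximise the count of defined stereo descriptors
(`b`/`t` entries without `?`), preferring structured over structureless
members, with deterministic lexicographic tie-break on (source, id).
Class IDs are ordinals over the classes sorted by their smallest member,
so identical inputs always yield identical IDs regardless of dump order.

## Reaction pipeline

Order of operations, which matters and is asserted by tests:

1. **alias application** — glycan-style alias IDs are rewritten to their
   canonical compound IDs (transitive, cycle-checked); compound records
   published under an alias are absorbed as synonyms of the target;
2. **placeholder splitting** — a reaction containing NAD(P)+/NAD(P)H (or
   the `…_OR_NO_P` spellings) stands for two reactions and is emitted as
   the NADP form under the original ID and the NAD form under ID+`_WOP`.
   Substitute cofactor records are looked up by name in the source, and
   synthesised as structureless records if absent (their reactions then
   balance as `undetermined` — exact, if less informative). A placeholder
   without its redox partner passes through unchanged with a warning;
3. **balance check** — performed *before* water/proton removal, per
   element, over neutral-parent formulas (the formula layer standard
   InChI prints before `/p`), taken from each participant's class
   representative. Charge is deliberately not checked: with neutral-parent
   formulas a charge mismatch surfaces as an H-count difference and is
   covered by the proton tolerance. A deficit of a·H + b·H2O (a, b ≥ 0)
   confined to one side is `balanced_tolerated`; the tolerance is strictly
   one-sided — an H deficit on one side combined with an H2O deficit on
   the other is `incomplete`. Deficits are reported as Hill formulas in
   Missing Substrate (left side short) / Missing Product (right side
   short). A lone O deficit is *not* water and stays `incomplete`.
   Symbolic coefficients (`n`) and formula-less participants give
   `undetermined`;
4. **small-species removal** — classes recognised as water or proton (by
   reduced key `H2O/h1H2`, or by normalized name in
   {h2o, water, h+, proton, hydron}) are removed from both sides. Their
   composition is known a priori, so a name-only proton record still
   participates in the balance check with formula H. A reaction whose side
   empties (e.g. water autoionisation) is excluded from matching, logged;
5. **reaction key** — each side becomes the sorted multiset of
   (class id, coefficient-as-text); the lexicographically smaller side is
   placed first, so a reaction and its reversed writing collide. The
   original direction arrows are preserved per member record for the
   output. Coefficients participate in identity (A = 2B ≠ A = 3B), and a
   symbolic `n` matches only another `n`.

## Merging and statistics

One merged reaction per key; members keep per-source ID lists (including
`_WOP` IDs and within-source duplicates). EC sets are unioned without
conflict resolution — one database attaches several EC numbers to a single
reaction ID where another splits them, so multi-EC unique reactions are
expected, and the (EC, reaction)-combination count is correspondingly
larger than the unique-reaction count (EC-less reactions count once).
Pathway annotations are pass-through union. The merged balance status is
the best-documented member's, except that any `incomplete` member
downgrades the group — a modeler filtering for balanced reactions must not
silently include a broken writing of one. Unified IDs are zero-padded
ordinals over the sorted keys: identical input, identical output.

Overlap statistics assign each unique reaction to the Venn cell of sources
contributing members; cell totals are asserted to sum to the unique count
on every run (an invariant violation is an internal error, CLI exit 2).

## Synthetic benchmark

The generator builds surrogate metabolites — CHNO formula families
(`C_k H_{2k} O_k` sugars, alcohols, aldehydes, hydrates) with exact
formulas, syntactically valid fabricated InChI layers, stereo layers on
the larger sugars, and per-compound name pools with Greek/hyphen/case
variants — plus water, a name-only proton, the four nicotinamide
cofactors (oxidised/reduced differing by H2 so redox reactions balance)
and optional generic name-only compounds. Base reactions (condensations,
hydrations, cofactor redox pairs) are element-balanced by construction;
every perturbation a real integration faces is then applied per source at
configurable rates, with truth labels recorded: synonym renaming, surface
noise, `/p` protonation variants, stereo-stripped republication, added
waters/protons, reversed equations, within-source duplicates, glycan
aliases, NAD(P)(H) placeholder collapse, dropped structures, and balance
corruption by deleting one CH2O unit from a product (expected deficit
CH2O on the product side).

Default conditions: 3 sources, 18 base reactions, ~28 base metabolites,
moderate perturbation rates (0.15–0.5 per site); the balance-QC corpus
uses 200 base reactions in one source so every status arises in numbers.
These sizes keep the full test suite and the acceptance script in the
low seconds while exercising every code path; recovery is scored over 20
seeds.

Scoring is pairwise precision/recall/F1 of co-membership against the
recorded truth (computed from the contingency table; a brute-force pair
enumeration cross-checks it in the tests), plus an expected-vs-computed
balance confusion matrix in which deficit formulas must also match.

What passing does **not** show about real data: the generator's name
pools are collision-free by default (real synonym collisions exist — the
guard is exercised by a dedicated collision mode and unit tests, not by
the recovery benchmark); its InChIs are clean standard-form strings (no
converter disagreements, no non-standard forms); structures, when present,
are internally consistent across sources; and the reaction repertoire is
a toy grammar, not a metabolic network topology. Recovery = 1.0 here
means the machinery is lossless under the modelled obstacles, not that
real-database integration is error-free.

## Known limitations

- Tautomers merge only insofar as standard InChI's mobile-H layer already
  collapses them; distinct fixed-H tautomer InChIs merge only by synonym.
- Partially-defined stereochemistry is never relaxed (see above).
- The name tier guard refuses structure-conflicting merges but cannot
  detect a *wrong* merge between two structureless records sharing an
  ambiguous name.
- EC numbers are carried, not validated; SPONTANEOUS is an opaque label.
- `n`-coefficient reactions match only syntactically identical writings.
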