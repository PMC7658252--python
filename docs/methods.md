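# Methods

## Pipeline

`synforge` enumerates one-step, two-reactant syntheses: prepared building
blocks are matched to the two reactant roles of each transform, all member
pairs are enumerated, the product template is applied, and the candidate
product is scored by the transform's clauses. The run is strictly forward:
the template is applied once and the clauses are evaluated on the two
reactants and the raw product in a single pass. The observable contract per
candidate is (product, clause delta, optional KILL); a KILL removes the
reaction from the product set but keeps it in the audit log with its
triggering clause, since computationally failed reactions are themselves
useful data (e.g. for training reactivity models).

## Rule format and scoring semantics

A transform is a YAML mapping: integer id, name, two role SMARTS, one SMIRKS
product template (two reactants, one product), declared leaving-group
fragments, a ring-forming flag, ordered scoring clauses, and free-form
metadata (typical yield, conditions) that the engine never interprets. The
expert-system origins of this rule style include rich control flow and
physico-chemical tests; here the generative semantics are reduced to what the
scoring actually needs — pattern tests plus ADD/SUBTRACT/KILL arithmetic — so
the rule format is declarative rather than a programming language. Named
property predicates are a closed vocabulary (`heavy_atoms`, `ring_count`,
`net_charge` with a comparator and threshold); open-ended computed-property
tests are out of scope.

Clause evaluation order is file order. The delta is a pure sum, so order
never changes the outcome, but the trace records clauses in order to keep
runs reproducible and auditable. ADD/SUBTRACT values are qualitative expert
judgements, conventionally multiples of five between 5 and 30; the loader
enforces this unless its permissive flag is set. Classification uses the
clause delta only: `Plus` for Δ > 0, otherwise `Neg n` with the largest
n ∈ {0, 10, 20, 30} not exceeding |Δ| (so 0 and −5 map to `Neg0`, −10/−15 to
`Neg10`, −20/−25 to `Neg20`, −30 and below to `Neg30`). The mapping of the
−5, −15, −25 deltas into the *lower* penalty bin is an interpretation of
"penalized by at least n" fixed here once; a transform's baseline quality
score, if present, is carried as metadata and deliberately excluded from
classification, which bins the sign and depth of the structural modifiers.

The shipped set contains eight rules spanning the common coupling classes —
amide and sulfonamide Schotten-Baumann couplings, biaryl (Suzuki-type)
cross-coupling, Williamson ether synthesis, Cu-catalyzed azide–alkyne
cycloaddition, Buchwald–Hartwig-type aryl amination, ester formation — plus a
Paal–Knorr pyrrole synthesis as a second ring former. Their clauses encode
standard practitioner judgements (thiols poison Pd and Cu catalysts;
anilines acylate sluggishly; ortho substitution slows cross-coupling;
tert-alkyl amines are severely hindered) and are chosen so that toy runs
populate every class and exercise KILL.

## Building-block preparation

Standardization keeps the largest organic fragment, normalizes functional
groups and neutralizes charges (RDKit `MolStandardize`). The unique key is
the isomeric canonical SMILES of the canonical tautomer, computed with
stereo-preserving tautomer settings: keto/enol pairs of one compound merge,
enantiomers stay distinct. Filters reject (in order) explicit isotope labels,
atoms outside {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I} — boron and silicon
stay because boronates and silanes are required coupling partners — and Bertz
complexity above a configurable cutoff (default 1000; typical catalog blocks
sit in the 100–800 range, so the default only removes structures too baroque
to be sensible screening precursors).

Role assignment counts symmetry-distinct match sites by uniquifying
substructure matches on their atom set: a pattern that matches the same atoms
in two orientations (e.g. N-C-C-N on ethylenediamine) is one site, while two
physically different sites (benzene-1,3-diamine against an amine role) are
two, and exclude the block. Dual-role exclusion is applied before multi-site
exclusion, and a dual-role block is recorded in both roles' exclusion lists.

## Protecting groups

Seven groups are handled: Boc, Fmoc, Cbz (amines), tert-butyl and benzyl
esters (carboxyls), tert-butyl ether and benzoate (hydroxyls). Benzyl ester
and benzoate are distinguished by the attachment-side atom (acyl carbon on
the substrate vs. ether oxygen on the substrate). Building blocks are never
modified — a protected block reacts, if at all, through another free group —
but every saved product is deprotected by applying removal templates until no
group is detected, each template stripping its group as one fragment (no
partial-removal intermediates). Ids record the outcome (`-DP` vs `-UN`).
When a protected and an unprotected twin of a block both react with the same
partner, both reaction records are kept (they are different proposed
syntheses) and the duplicate deprotected product counts once in
unique-product totals.

## Annotation

Descriptors are computed with RDKit on the re-canonicalized structure, so
annotations are exact functions of the canonical structure: molecular weight,
Crippen atom-contribution logP (the method name is recorded in output
metadata; production systems have used other logP parameterizations),
Ertl TPSA, fraction of sp³ carbons, strict rotatable bonds, Lipinski H-bond
donor/acceptor counts, rule-of-five violations (MW > 500, logP > 5, HBD > 5,
HBA > 10), rule-of-three violations (MW > 300, logP > 3, HBD > 3,
rotatable > 3, TPSA > 60), PAINS matches (RDKit's bundled published catalog),
and QED with the published mean-weight desirability set. The demerit score is
an additive total over substructure alert rules with per-rule penalty values,
flagged against the conventional strict (<100) and loose (<160) limits; the
shipped rule file is a representative synthetic subset (~24 rules) and the
loader accepts any file of the same shape, so a complete published alert set
can be dropped in.

## Library analytics

With N blocks and T two-reactant transforms the theoretical product maximum
is ½·N²·T — the unordered-pair convention, since A+B and B+A give the same
product and ordered double-counting is removed during pair generation. The
success ratio is that maximum over the saved count (displayed at two
significant figures); the KILL loss rate is 1 − saved/tested. The
SAR-neighbor estimate projects products onto the flattened N×N matrix of
matched blocks: fill = saved/(½N²), and a product has about N·fill neighbors
sharing one of its two blocks. On the shipped production-scale count table
the formula gives ≈ 24,400 mean neighbors from a 17% fill of the 143,365²/2
matrix; accounts of that run quote "about 24,800", which its own printed
intermediates (143,365 × 17%) do not reproduce — the package reports the
formula result.

A ring system is a connected component of ring atoms and ring bonds, so fused
and spiro systems count once; atoms double-bonded to a ring (carbonyl oxygen
on a ring) are excluded by default because the ring-system operator is not
standardized — an `include_exocyclic_double` flag pulls them in. Systems are
identified by the canonical SMILES of the extracted ring-only substructure.
Database overlap is exact set intersection on the same tautomer-insensitive,
stereo-sensitive unique keys used for deduplication.

## Toy library generator

The generator emulates a purchasable building-block pool at desk scale:
eleven functional-group classes (default 205 blocks: 30 acids, 25 primary and
10 secondary amines, 25 aryl bromides, 20 boronic acids, 15 azides, 15
terminal alkynes, 25 alcohols, 10 sulfonyl chlorides, 10 alkyl bromides, 10
1,4-diketones, 10 decoys), built by decorating per-class scaffold templates
with a fixed pool of 24 inert tails; randomness (seeded) only selects
decorations, so every molecule is valid by construction and generation is
deterministic. Twenty percent of acids, amines, alcohols and aryl bromides
carry a real protecting group; for acids, alcohols and aryl bromides the
protected variants keep a second free reacting group so deprotected products
arise in runs. Planted records provide ground truth: a dual-role amino acid,
a multi-site diamine, KILL exercisers (thiol amine, aminophenol, amino
alcohol, hindered amines, an ortho-disubstituted acid), and three deliberate
rejects (isotope label, organotin, an over-complex polycycle).

What the toy library does *not* emulate: real catalog property distributions,
salt forms beyond simple counterions, reagent availability or price, and the
long tail of rare functional groups. Passing tests therefore demonstrate the
correctness of the machinery (standardization, exclusions, template
application, scoring arithmetic, deprotection, bookkeeping identities), not
the chemical yield realism of the shipped clause values, which remain
qualitative expert judgements.

## Numerical and design choices

- Display conventions: percentages to two decimals, success ratio to two
  significant figures, theoretical maximum to the nearest billion at
  production scale.
- Determinism: transforms run in id order, pairs in sorted block-id order,
  product ids are sequential; two runs on identical inputs produce
  byte-identical product tables.
- A pair whose template application yields more than one distinct sanitized
  product would be ambiguous; multi-site exclusion makes this unreachable for
  the shipped rules (covered by a test), and the engine audits and discards
  such candidates (`ambiguous_product`) rather than aborting, since
  user-supplied templates can match more broadly than their role patterns.
- Single-reaction failures (template mismatch, sanitization failure,
  deprotection failure) are audited and never abort a run.
- Desk-scale problem sizes are a package choice: the default toy run tests
  ~4,400 pairs across eight transforms in well under a minute, large enough
  to populate every class and every audit path while keeping the suite fast.

## Known limitations

Single-step, two-reactant syntheses only; no intramolecular application of
coupling transforms (polymer/macrocycle ambiguity); no protection planning
(groups are only removed); the shipped demerit subset is illustrative, not
the full published alert set; clause values are qualitative and uncalibrated
against experimental yields; process-level parallelism is not implemented —
the enumeration is embarrassingly parallel and desk-scale runs do not need
it.
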