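# synforge

Forward-synthesis virtual library generation with expert-system reaction
rules.

## The problem

Virtual screening collections built by enumerating molecular graphs carry no
synthesis route, so most hits are expensive or impossible to make. The
forward-synthetic alternative asks the opposite question — *what can be made
easily from stock starting materials?* — and enumerates one-step, two-reactant
couplings over a pool of purchasable building blocks, keeping only reactions
an expert rule set judges feasible. `synforge` implements that pipeline at
desk scale for computational chemists who want scored, classified, annotated
virtual products with a full audit trail.

## The model

A **transform** encodes one reaction chemistry as:

- two reactant **role patterns** (SMARTS) for roles A and B,
- a **product template** (SMIRKS) mapping one A-match plus one B-match to a
  single product, with declared leaving groups so that
  heavy(P) = heavy(A) + heavy(B) − heavy(leaving) holds for every saved
  reaction,
- an ordered list of **scoring clauses**. Each clause tests a substructure or
  named property on reactant A, reactant B, or the product and then either
  **ADD**s or **SUBTRACT**s a value *v* ∈ {5, 10, …, 30} from the reaction
  score, or **KILL**s the reaction outright.

For a pool of *N* building blocks and *T* transforms, all |A|·|B| reactant
pairs per transform are enumerated after two exclusions: blocks matching both
roles (would oligomerize) and blocks matching one role at more than one
symmetry-distinct site (would give mixtures). The net clause delta Δ assigns
each saved reaction a synthesizability class:

    Plus   if Δ > 0
    Neg n  otherwise, with n = max{0,10,20,30 : n ≤ |Δ|}

Products are stored deprotected (seven standard protecting groups: Boc, Fmoc,
Cbz, *t*-Bu/benzyl esters, *t*-Bu ether, benzoate), with ids suffixed `-DP`
when a group was removed and `-UN` otherwise. Library-level accounting uses
the theoretical maximum ½·N²·T (unordered pairs), the success ratio
(maximum / saved), and a SAR-neighbor estimate N·fill where
fill = saved / (½·N²).

## Worked example

```python
from rdkit import Chem
from synforge import builtin_rules
from synforge.engine import apply_transform, score_reaction, classify_score
from synforge.deprotect import deprotect, suffix_id

amide = next(t for t in builtin_rules() if "Amide" in t.name)
acid = Chem.MolFromSmiles("CC(C)(C)OC(=O)NCCC(=O)O")   # Boc-protected amino acid
amine = Chem.MolFromSmiles("NCCc1ccccc1")

product, _ = apply_transform(amide, acid, amine)
delta, trace = score_reaction(amide, acid, amine, Chem.MolFromSmiles(product))
free, removed = deprotect(product)
print(product, trace, delta, classify_score(delta), free, suffix_id("P0000001", removed))
```

prints

```
CC(C)(C)OC(=O)NCCC(=O)NCCc1ccccc1
[(2, 'ADD', 10), (6, 'ADD', 5)]
15 Plus
NCCC(=O)NCCc1ccccc1
P0000001-DP
```

The coupling succeeds; two ADD clauses fire (+10 unhindered primary aliphatic
amine, +5 aliphatic acid) for a net +15, so the reaction lands in the `Plus`
class; the Boc group rides through the reaction and is stripped from the
stored product, whose id therefore carries `-DP`. The `examples/` directory
has one short script per capability (library preparation, scoring, full runs,
annotation, analytics); `synforge --help` exposes the same stages as a CLI
(`gen-bbs`, `prep-bbs`, `match`, `enumerate`, `annotate`, `report`). Product
tables are written as CSV and SDF (namespaced `SF_*` data fields: product id,
transform id, reactant ids, delta, class, protected form), with killed
reactions retained in a JSON-lines audit log.

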