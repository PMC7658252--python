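"""Apply one reaction rule to one reactant pair and walk through the scoring.

A transform couples two role patterns to a product template and carries
ADD/SUBTRACT/KILL clauses; the net clause delta decides the synthesizability
class (Plus if positive, otherwise Neg0/10/20/30 by penalty depth).
"""

from rdkit import Chem

from synforge import builtin_rules
from synforge.deprotect import deprotect, suffix_id
from synforge.engine import KILLED, apply_transform, classify_score, score_reaction

amide = next(t for t in builtin_rules() if "Amide" in t.name)
acid = Chem.MolFromSmiles("CC(C)(C)OC(=O)NCCC(=O)O")  # Boc-protected amino acid
amine = Chem.MolFromSmiles("NCCc1ccccc1")  # phenethylamine

product, reason = apply_transform(amide, acid, amine)
print(f"raw product: {product}  (failure reason: {reason})")

outcome = score_reaction(amide, acid, amine, Chem.MolFromSmiles(product))
assert outcome[0] is not KILLED
delta, trace = outcome
print(f"clause trace: {trace}")
print(f"net delta {delta:+d} -> class {classify_score(delta)}")

free, removed = deprotect(product)
print(f"deprotected product: {free}  (removed {removed})")
print(f"product id: {suffix_id('P0000001', removed)}")
# The Boc group rides through the coupling and is stripped afterwards, so the
# stored product is the free amine and its id carries the -DP suffix.
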