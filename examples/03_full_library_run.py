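"""Run the full pipeline: toy library x shipped rule set, with bookkeeping.

Prints per-transform success rates (saved / tested pairs) and the library-wide
class distribution, whose saved counts partition the total.
"""

from synforge import builtin_rules, prepare
from synforge.analysis import class_distribution
from synforge.engine import run_library
from synforge.fixtures import DEFAULT_SPEC, generate_library

library = generate_library(DEFAULT_SPEC)
blocks = prepare([(r.bb_id, r.smiles) for r in library])
result = run_library(builtin_rules(), blocks)

print("per-transform outcomes:")
for tid, pt in result.stats.per_transform.items():
    print(
        f"  {tid}  {pt['name'][:42]:<42} tested {pt['tested_pairs']:>5}"
        f"  killed {pt['killed']:>3}  saved {pt['saved']:>5}"
        f"  rate {pt['success_rate']:.2f}"
    )

totals = result.stats.totals
print(f"\ntotal: {totals['tested_pairs']} pairs tested, {totals['killed']} killed, "
      f"{totals['saved']} saved, {totals['unique_combined']} unique products")

print("\nclass distribution (percent of saved reactions):")
print(class_distribution(result.records).to_string(index=False))
# The success rate is the fraction of enumerated reactant pairs that survive
# the KILL clauses; the class split shows how the ADD/SUBTRACT judgements
# stratify the saved reactions by predicted synthesizability.
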