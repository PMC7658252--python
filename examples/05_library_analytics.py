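"""Library-level analytics: closed-form estimates, ring census, overlap.

The closed-form estimates are exercised on the shipped production-scale count
table (billions of saved reactions from ~150k catalog blocks and 53 rules);
the ring census and overlap run on a desk-scale pipeline product set.
"""

from synforge import builtin_rules, prepare
from synforge.analysis import (
    kill_loss_rate,
    load_reference_run,
    overlap,
    ring_system_census,
    round_sig,
    sar_neighbors,
    success_ratio,
    theoretical_max,
)
from synforge.engine import run_library
from synforge.fixtures import DEFAULT_SPEC, generate_library

ref = load_reference_run()
total = ref["total_saved"]
t_max = theoretical_max(ref["accepted_bbs"], ref["n_transforms"])
print(f"theoretical max: 0.5 * {ref['accepted_bbs']}^2 * {ref['n_transforms']} "
      f"= {t_max:.3e}  (~{round(t_max / 1e9)} billion)")
print(f"success ratio: 1/{round_sig(success_ratio(t_max, total), 2):.0f} "
      f"of the theoretical maximum was actually saved")
print(f"KILL loss rate: {kill_loss_rate(ref['tested_pairs'], total):.0%} of tested pairs")
fill, mean = sar_neighbors(ref["matched_bbs"], total)
print(f"SAR neighbors: {fill:.0%} matrix fill -> ~{mean:,.0f} products sharing "
      f"a building block with any given product")

# desk-scale census and overlap
library = generate_library(DEFAULT_SPEC)
blocks = prepare([(r.bb_id, r.smiles) for r in library])
result = run_library(builtin_rules(), blocks)
census = ring_system_census(rec.product_smiles for rec in result.records)
print(f"\ntoy run: {len(census.systems)} unique ring systems across "
      f"{sum(census.counts.values())} instances; most common:")
for system, count in census.counts.most_common(3):
    print(f"  {system}  x{count}")

bb_keys = {b.unique_key for b in blocks if b.rejected is None}
product_keys = {rec.product_key for rec in result.records}
common, _, _ = overlap(product_keys, bb_keys)
print(f"products identical to an input building block: {common}")
# A nonzero overlap with the input pool is expected whenever the catalog
# contains blocks that are themselves simple coupling products.
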