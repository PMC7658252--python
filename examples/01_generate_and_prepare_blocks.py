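"""Generate a seeded toy building-block library and prepare it for enumeration.

Preparation standardizes each SMILES (largest organic fragment, neutralized),
detects protecting groups, filters isotopes/metals/over-complex structures,
and deduplicates on a stereo-sensitive, tautomer-insensitive key.
"""

from collections import Counter

from synforge import prepare
from synforge.fixtures import DEFAULT_SPEC, generate_library

library = generate_library(DEFAULT_SPEC)
print(f"generated {len(library)} building blocks (seed {DEFAULT_SPEC.seed})")

blocks = prepare([(r.bb_id, r.smiles) for r in library])
accepted = [b for b in blocks if b.rejected is None]
rejected = Counter(b.rejected for b in blocks if b.rejected is not None)

print(f"accepted {len(accepted)} blocks after standardization + filters")
print(f"rejected by reason: {dict(rejected)}")
protected = [b for b in accepted if b.protecting_groups]
print(f"{len(protected)} accepted blocks carry protecting groups, e.g.:")
for b in protected[:3]:
    print(f"  {b.bb_id}  {b.smiles_std}  PGs={b.protecting_groups}")
# Rejections are deliberate plants (isotope label, organometallic, over-complex
# polycycle); everything else in the toy library is valid by construction.
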