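# Bookkeeping numbers from the production-scale release run of this kind of
# forward-synthesis pipeline (billions of products from ~150k catalog blocks
# and 53 transforms).  Used as INPUTS by the report formatter and the
# closed-form estimates; nothing here is computed by this package.
accepted_bbs: 152532
matched_bbs: 143365
n_transforms: 53
tested_pairs: 3.59e+9
class_counts:
  Plus:  {saved: 1094782440, unique: 976051945}
  Neg0:  {saved: 609262,     unique: 579532}
  Neg10: {saved: 54775204,   unique: 48036148}
  Neg20: {saved: 82180372,   unique: 80366188}
  Neg30: {saved: 516116725,  unique: 457508945}
total_saved: 1748464003
unique_combined: 1526316392
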