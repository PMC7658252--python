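# Protecting-group definitions: detection SMARTS, removal SMIRKS, attachment class.
# attach_index points at the substrate-side atom within the SMARTS match
# (the nitrogen for amine PGs, the acyl carbon for carboxyl PGs, the ether
# oxygen's carbon for hydroxyl PGs).
protecting_groups:
  - label: Boc
    attach_class: amine
    smarts: "[NX3][CX3](=O)OC(C)(C)C"
    removal: "[NX3:1]C(=O)OC(C)(C)C>>[N:1]"
    attach_index: 0
  - label: Fmoc
    attach_class: amine
    smarts: "[NX3][CX3](=O)OCC1c2ccccc2-c2ccccc21"
    removal: "[NX3:1]C(=O)OCC1c2ccccc2-c2ccccc21>>[N:1]"
    attach_index: 0
  - label: Cbz
    attach_class: amine
    smarts: "[NX3][CX3](=O)OCc1ccccc1"
    removal: "[NX3:1]C(=O)OCc1ccccc1>>[N:1]"
    attach_index: 0
  - label: tBu_ester
    attach_class: carboxyl
    smarts: "[#6][CX3](=O)[OX2]C(C)(C)C"
    removal: "[#6:1][C:2](=[O:3])[O:4]C(C)(C)C>>[#6:1][C:2](=[O:3])[O:4][H]"
    attach_index: 1
  - label: Bn_ester
    attach_class: carboxyl
    smarts: "[#6][CX3](=O)[OX2][CH2]c1ccccc1"
    removal: "[#6:1][C:2](=[O:3])[O:4][CH2]c1ccccc1>>[#6:1][C:2](=[O:3])[O:4][H]"
    attach_index: 1
  - label: tBu_ether
    attach_class: hydroxyl
    smarts: "[#6;!$([CX3]=O)][OX2]C(C)(C)C"
    removal: "[#6;!$([CX3]=O):1][O:2]C(C)(C)C>>[#6:1][O:2][H]"
    attach_index: 0
  - label: Bz_O
    attach_class: hydroxyl
    smarts: "[#6;!$([CX3]=O)][OX2]C(=O)c1ccccc1"
    removal: "[#6;!$([CX3]=O):1][O:2]C(=O)c1ccccc1>>[#6:1][O:2][H]"
    attach_index: 0
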