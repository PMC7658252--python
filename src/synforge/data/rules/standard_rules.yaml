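# Standard shipped rule set: eight two-reactant transforms spanning the
# common coupling classes plus two ring formers.  Clause values are
# qualitative expert judgements in increments of five (5-30); KILL vetoes the
# reaction outright.  Leaving groups are declared as SMILES fragments so atom
# bookkeeping (heavy atoms in = heavy atoms out + leaving) can be audited.
transforms:
  - id: 1101
    name: Amide coupling (Schotten-Baumann type)
    ring_forming: false
    role_a: "[CX3](=O)[OX2H1]"
    role_b: "[NX3;H2,H1;!$([NX3][CX3]=[OX1]);!$([NX3][!#6;!#1])]"
    product_template: "[C:1](=[O:2])[OX2H1].[NX3;H2,H1:3]>>[C:1](=[O:2])[N:3]"
    leaving_groups: ["O"]
    metadata: {typical_yield: "70-95%", conditions: "coupling agent, base, RT"}
    clauses:
      - {scope: reactant_a, action: KILL, smarts: "[CX3](=O)[Cl,Br]"}         # acyl halide present: uncontrolled acylation
      - {scope: reactant_b, action: KILL, smarts: "[SX2H]"}                   # free thiol competes with the amine
      - {scope: reactant_b, action: ADD, value: 10, smarts: "[NX3H2][CX4]"}   # unhindered primary aliphatic amine
      - {scope: reactant_b, action: SUBTRACT, value: 10, smarts: "[NX3;H2,H1]c"}  # aryl amine: weak nucleophile
      - {scope: reactant_b, action: SUBTRACT, value: 30, smarts: "[NX3H2][CX4H0]"}  # amine on quaternary carbon: severe hindrance
      - {scope: reactant_a, action: SUBTRACT, value: 15, smarts: "[OX2H1]C(=O)c1c([!H])cccc1"}  # ortho-substituted benzoic acid
      - {scope: reactant_a, action: ADD, value: 5, smarts: "[CX4][CX3](=O)[OX2H1]"}  # aliphatic acid
      - {scope: product, action: SUBTRACT, value: 5, property: heavy_atoms, op: gt, threshold: 40}

  - id: 1102
    name: Sulfonamide formation (Schotten-Baumann)
    ring_forming: false
    role_a: "[SX4](=O)(=O)[Cl]"
    role_b: "[NX3;H2,H1;!$([NX3][CX3]=[OX1]);!$([NX3][!#6;!#1])]"
    product_template: "[S:1](=[O:2])(=[O:3])[Cl].[NX3;H2,H1:4]>>[S:1](=[O:2])(=[O:3])[N:4]"
    leaving_groups: ["Cl"]
    metadata: {typical_yield: "75-95%", conditions: "base, 0 C to RT"}
    clauses:
      - {scope: reactant_b, action: KILL, smarts: "[OX2H]c"}                  # phenol competes for the sulfonyl chloride
      - {scope: reactant_b, action: ADD, value: 10, smarts: "[NX3H2][CX4]"}
      - {scope: reactant_b, action: SUBTRACT, value: 10, smarts: "[NX3;H2,H1]c"}
      - {scope: reactant_b, action: SUBTRACT, value: 20, smarts: "[NX3H2][CX4H0]"}
      - {scope: reactant_a, action: ADD, value: 5, smarts: "c[SX4](=O)(=O)[Cl]"}  # aryl sulfonyl chlorides are robust

  - id: 1103
    name: Biaryl cross-coupling (aryl bromide + boronic acid, Suzuki type)
    ring_forming: false
    role_a: "[c][Br]"
    role_b: "[c][B]([OX2H])[OX2H]"
    product_template: "[c:1][Br].[c:2][B]([OX2H])[OX2H]>>[c:1][c:2]"
    leaving_groups: ["Br", "OBO"]
    metadata: {typical_yield: "60-95%", conditions: "Pd catalyst, base, heat"}
    clauses:
      - {scope: reactant_b, action: KILL, smarts: "[SX2H]"}                   # thiols poison the Pd catalyst
      - {scope: reactant_a, action: KILL, smarts: "[SX2H]"}
      - {scope: reactant_b, action: ADD, value: 10, smarts: "c[B]([OX2H])[OX2H]"}
      - {scope: reactant_a, action: SUBTRACT, value: 10, smarts: "Brc:[c;!H1]"}   # ortho substitution slows transmetalation
      - {scope: reactant_b, action: SUBTRACT, value: 10, smarts: "OB(O)c:[c;!H1]"}

  - id: 1104
    name: Williamson ether synthesis
    ring_forming: false
    role_a: "[CX4;H2,H1][Br]"
    role_b: "[CX4][OX2H1]"
    product_template: "[CX4:1][Br].[OX2H1:2][CX4:3]>>[CX4:1][O:2][CX4:3]"
    leaving_groups: ["Br"]
    metadata: {typical_yield: "50-85%", conditions: "strong base"}
    clauses:
      - {scope: reactant_b, action: KILL, smarts: "[NX3;H2,H1]"}              # free amine is alkylated instead
      - {scope: reactant_a, action: ADD, value: 10, smarts: "[CH2](Br)c"}     # benzylic halide: activated
      - {scope: reactant_a, action: SUBTRACT, value: 10, smarts: "[CX4H1]Br"} # secondary halide: elimination competes
      - {scope: product, action: SUBTRACT, value: 5, property: heavy_atoms, op: gt, threshold: 40}

  - id: 1105
    name: Azide-alkyne cycloaddition (copper catalyzed)
    ring_forming: true
    role_a: "[#6][NX2]=[NX2+]=[NX1-]"
    role_b: "[#6][CX2]#[CX2H1]"
    product_template: "[#6:4][N:1]=[N+:2]=[N-:3].[#6:7][C:6]#[CH1:5]>>[#6:4][n:1]1[n+0:2][n+0:3][c:6]([#6:7])[cH:5]1"
    leaving_groups: []
    metadata: {typical_yield: "80-99%", conditions: "Cu(I), RT"}
    clauses:
      - {scope: reactant_b, action: KILL, smarts: "[SX2H]"}                   # thiols sequester Cu(I)
      - {scope: reactant_b, action: ADD, value: 10, smarts: "c[CX2]#[CX2H1]"} # aryl-conjugated terminal alkyne
      - {scope: reactant_a, action: ADD, value: 5, smarts: "[CX4][NX2]=[NX2+]=[NX1-]"}  # alkyl azide
      - {scope: product, action: SUBTRACT, value: 5, property: heavy_atoms, op: gt, threshold: 45}

  - id: 1106
    name: Aryl amination (aryl bromide + amine, Buchwald-Hartwig type)
    ring_forming: false
    role_a: "[c][Br]"
    role_b: "[NX3;H2,H1;!$([NX3][CX3]=[OX1]);!$([NX3][!#6;!#1])]"
    product_template: "[c:1][Br].[NX3;H2,H1:2]>>[c:1][N:2]"
    leaving_groups: ["Br"]
    metadata: {typical_yield: "50-90%", conditions: "Pd catalyst, ligand, base"}
    clauses:
      - {scope: reactant_a, action: KILL, smarts: "[SX2H]"}
      - {scope: reactant_b, action: KILL, smarts: "[SX2H]"}
      - {scope: reactant_b, action: ADD, value: 10, smarts: "[NX3H1]([CX4])[CX4]"}  # secondary dialkyl amine
      - {scope: reactant_a, action: SUBTRACT, value: 10, smarts: "Brc:[c;!H1]"}
      - {scope: reactant_b, action: SUBTRACT, value: 10, smarts: "[CX3](=O)[OX2H1]"}  # free acid chelates the catalyst
      - {scope: reactant_b, action: SUBTRACT, value: 10, smarts: "[NX3;H2,H1]c"}

  - id: 1107
    name: Ester formation (acid + alcohol)
    ring_forming: false
    role_a: "[CX3](=O)[OX2H1]"
    role_b: "[CX4][OX2H1]"
    product_template: "[C:1](=[O:2])[OX2H1].[OX2H1:3][CX4:4]>>[C:1](=[O:2])[O:3][CX4:4]"
    leaving_groups: ["O"]
    metadata: {typical_yield: "60-90%", conditions: "acid catalysis or coupling agent"}
    clauses:
      - {scope: reactant_b, action: KILL, smarts: "[OX2H1][CX4H0]"}           # tertiary alcohol barely esterifies
      - {scope: reactant_a, action: ADD, value: 10, smarts: "[CX4][CX3](=O)[OX2H1]"}
      - {scope: reactant_b, action: ADD, value: 5, smarts: "[CX4H2][OX2H1]"}  # primary alcohol
      - {scope: reactant_b, action: SUBTRACT, value: 10, smarts: "[NX3;H2,H1]"}  # free amine: aminolysis competes
      - {scope: product, action: SUBTRACT, value: 5, property: heavy_atoms, op: gt, threshold: 40}

  - id: 1108
    name: Pyrrole synthesis (1,4-diketone + primary amine, Paal-Knorr)
    ring_forming: true
    role_a: "[#6][CX3](=O)[CH2X4][CH2X4][CX3](=O)[#6]"
    role_b: "[NX3H2][#6;!$([CX3]=[OX1])]"
    product_template: "[#6:1][C:2](=[O:3])[CH2:4][CH2:5][C:6](=[O:7])[#6:8].[NX3H2:9][#6:10]>>[#6:1][c:2]1[cH:4][cH:5][c:6]([#6:8])[n:9]1[#6:10]"
    leaving_groups: ["O", "O"]
    metadata: {typical_yield: "50-90%", conditions: "acid catalysis, heat"}
    clauses:
      - {scope: reactant_b, action: KILL, smarts: "[SX2H]"}
      - {scope: reactant_b, action: ADD, value: 10, smarts: "[NX3H2][CX4]"}
      - {scope: reactant_b, action: SUBTRACT, value: 10, smarts: "[NX3H2]c"}  # aryl amine: sluggish condensation
      - {scope: product, action: ADD, value: 5, property: ring_count, op: ge, threshold: 2}
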