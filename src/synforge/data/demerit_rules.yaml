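# Representative SYNTHETIC subset of additive substructure demerit rules for
# flagging potentially reactive or assay-interfering compounds (lower total is
# better; conventional cutoffs: <100 strict, <160 loose).  This file is a
# demonstration rule set authored for this package — it is NOT the full
# published 275-rule collection.  Drop in a complete rule file of the same
# shape to use one.
rules:
  - {id: acyl_halide,        smarts: "[CX3](=O)[Cl,Br,I]",                    demerits: 100, description: acylating agent}
  - {id: sulfonyl_halide,    smarts: "[SX4](=O)(=O)[Cl,Br]",                  demerits: 100, description: sulfonylating agent}
  - {id: isocyanate,         smarts: "[NX2]=[CX2]=[OX1]",                     demerits: 100, description: isocyanate}
  - {id: isothiocyanate,     smarts: "[NX2]=[CX2]=[SX1]",                     demerits: 100, description: isothiocyanate}
  - {id: aldehyde,           smarts: "[CX3H1](=O)[#6]",                       demerits: 50,  description: aldehyde}
  - {id: epoxide,            smarts: "C1OC1",                                 demerits: 75,  description: epoxide}
  - {id: aziridine,          smarts: "C1NC1",                                 demerits: 75,  description: aziridine}
  - {id: michael_acceptor,   smarts: "[CX3]=[CX3][CX3](=O)[#6]",              demerits: 50,  description: enone Michael acceptor}
  - {id: alkyl_halide,       smarts: "[CX4][Cl,Br,I]",                        demerits: 50,  description: alkylating agent}
  - {id: azide,              smarts: "[NX2]=[NX2+]=[NX1-]",                   demerits: 75,  description: azide}
  - {id: diazo,              smarts: "[CX3]=[NX2+]=[NX1-]",                   demerits: 100, description: diazo compound}
  - {id: nitro_aromatic,     smarts: "c[N+](=O)[O-]",                         demerits: 25,  description: aromatic nitro}
  - {id: nitro_aliphatic,    smarts: "[CX4][N+](=O)[O-]",                     demerits: 50,  description: aliphatic nitro}
  - {id: thiol,              smarts: "[SX2H]",                                demerits: 50,  description: free thiol}
  - {id: hydrazine,          smarts: "[NX3;H2,H1][NX3;H2,H1]",                demerits: 50,  description: hydrazine}
  - {id: quinone,            smarts: "O=C1C=CC(=O)C=C1",                      demerits: 100, description: quinone}
  - {id: catechol,           smarts: "c1ccc(O)c(O)c1",                        demerits: 50,  description: catechol}
  - {id: anhydride,          smarts: "[CX3](=O)[OX2][CX3](=O)",               demerits: 100, description: anhydride}
  - {id: peroxide,           smarts: "[OX2][OX2]",                            demerits: 100, description: peroxide}
  - {id: n_oxide,            smarts: "[NX4+][O-]",                            demerits: 25,  description: N-oxide}
  - {id: boronic_acid,       smarts: "[#6][B]([OX2H])[OX2H]",                 demerits: 25,  description: boronic acid}
  - {id: rhodanine,          smarts: "O=C1CSC(=S)N1",                         demerits: 75,  description: rhodanine core}
  - {id: imine,              smarts: "[CX3]=[NX2][#6]",                       demerits: 25,  description: imine}
  - {id: phenol_multi,       smarts: "c1c(O)cc(O)cc1O",                       demerits: 50,  description: polyphenol}
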