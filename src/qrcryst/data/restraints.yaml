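# Default restraint dictionary (harmonic bonds/angles per residue).
# Ideal values measured from the fragment templates in qrcryst.fragments;
# regenerate with scripts/make_dictionary.py.  Units: Å, degrees,
# restraint-units Å^-2 / rad^-2.  Format per residue:
#   bonds:  [atom_i, atom_j, ideal_length, force_constant]
#   angles: [atom_i, apex, atom_k, ideal_degrees, force_constant]
nonbonded:
  k: 100.0
  rmin: 2.2
  rmin_metal: 1.7
residues:
  ASP:
    angles:
    - - OD1
      - CG
      - OD2
      - 123.0
      - 300.0
    - - OD1
      - CG
      - CB
      - 118.5
      - 300.0
    - - OD2
      - CG
      - CB
      - 118.5
      - 300.0
    - - CG
      - CB
      - HB1
      - 109.471221
      - 300.0
    - - CG
      - CB
      - HB2
      - 109.471221
      - 300.0
    - - CG
      - CB
      - HB3
      - 109.471221
      - 300.0
    - - HB1
      - CB
      - HB2
      - 109.471221
      - 300.0
    - - HB1
      - CB
      - HB3
      - 109.471221
      - 300.0
    - - HB2
      - CB
      - HB3
      - 109.471221
      - 300.0
    atoms:
    - OD1
    - CG
    - OD2
    - CB
    - HB1
    - HB2
    - HB3
    bonds:
    - - CG
      - OD1
      - 1.26
      - 2500.0
    - - CG
      - OD2
      - 1.26
      - 2500.0
    - - CG
      - CB
      - 1.52
      - 2500.0
    - - CB
      - HB1
      - 1.09
      - 3500.0
    - - CB
      - HB2
      - 1.09
      - 3500.0
    - - CB
      - HB3
      - 1.09
      - 3500.0
    charge: -1
  FE:
    angles: []
    atoms:
    - FE
    bonds: []
    charge: 0
  GLU:
    angles:
    - - OE1
      - CD
      - OE2
      - 123.0
      - 300.0
    - - OE1
      - CD
      - CG
      - 118.5
      - 300.0
    - - OE2
      - CD
      - CG
      - 118.5
      - 300.0
    - - CD
      - CG
      - HG1
      - 109.471221
      - 300.0
    - - CD
      - CG
      - HG2
      - 109.471221
      - 300.0
    - - CD
      - CG
      - HG3
      - 109.471221
      - 300.0
    - - HG1
      - CG
      - HG2
      - 109.471221
      - 300.0
    - - HG1
      - CG
      - HG3
      - 109.471221
      - 300.0
    - - HG2
      - CG
      - HG3
      - 109.471221
      - 300.0
    atoms:
    - OE1
    - CD
    - OE2
    - CG
    - HG1
    - HG2
    - HG3
    bonds:
    - - CD
      - OE1
      - 1.26
      - 2500.0
    - - CD
      - OE2
      - 1.26
      - 2500.0
    - - CD
      - CG
      - 1.52
      - 2500.0
    - - CG
      - HG1
      - 1.09
      - 3500.0
    - - CG
      - HG2
      - 1.09
      - 3500.0
    - - CG
      - HG3
      - 1.09
      - 3500.0
    charge: -1
  HIS:
    angles:
    - - CE1
      - NE2
      - CD2
      - 108.0
      - 300.0
    - - NE2
      - CD2
      - CG
      - 108.0
      - 300.0
    - - CD2
      - CG
      - ND1
      - 108.0
      - 300.0
    - - CG
      - ND1
      - CE1
      - 108.0
      - 300.0
    - - ND1
      - CE1
      - NE2
      - 108.0
      - 300.0
    - - CD2
      - CG
      - CB
      - 126.0
      - 300.0
    - - ND1
      - CG
      - CB
      - 126.0
      - 300.0
    - - CG
      - CD2
      - HD2
      - 126.0
      - 300.0
    - - NE2
      - CD2
      - HD2
      - 126.0
      - 300.0
    - - ND1
      - CE1
      - HE1
      - 126.0
      - 300.0
    - - NE2
      - CE1
      - HE1
      - 126.0
      - 300.0
    - - CG
      - ND1
      - HD1
      - 126.0
      - 300.0
    - - CE1
      - ND1
      - HD1
      - 126.0
      - 300.0
    - - CG
      - CB
      - HB1
      - 109.471221
      - 300.0
    - - CG
      - CB
      - HB2
      - 109.471221
      - 300.0
    - - CG
      - CB
      - HB3
      - 109.471221
      - 300.0
    - - HB1
      - CB
      - HB2
      - 109.471221
      - 300.0
    - - HB1
      - CB
      - HB3
      - 109.471221
      - 300.0
    - - HB2
      - CB
      - HB3
      - 109.471221
      - 300.0
    atoms:
    - NE2
    - CD2
    - CG
    - ND1
    - CE1
    - CB
    - HD2
    - HE1
    - HD1
    - HB1
    - HB2
    - HB3
    bonds:
    - - NE2
      - CD2
      - 1.37
      - 2500.0
    - - CD2
      - CG
      - 1.37
      - 2500.0
    - - CG
      - ND1
      - 1.37
      - 2500.0
    - - ND1
      - CE1
      - 1.37
      - 2500.0
    - - CE1
      - NE2
      - 1.37
      - 2500.0
    - - CG
      - CB
      - 1.5
      - 2500.0
    - - CD2
      - HD2
      - 1.08
      - 3500.0
    - - CE1
      - HE1
      - 1.08
      - 3500.0
    - - ND1
      - HD1
      - 1.01
      - 3500.0
    - - CB
      - HB1
      - 1.09
      - 3500.0
    - - CB
      - HB2
      - 1.09
      - 3500.0
    - - CB
      - HB3
      - 1.09
      - 3500.0
    charge: 0
  HOH:
    angles:
    - - H1
      - O
      - H2
      - 104.52
      - 300.0
    atoms:
    - O
    - H1
    - H2
    bonds:
    - - O
      - H1
      - 0.9572
      - 3500.0
    - - O
      - H2
      - 0.9572
      - 3500.0
    charge: 0
  HYD:
    angles: []
    atoms:
    - O
    - H1
    bonds:
    - - O
      - H1
      - 0.96
      - 3500.0
    charge: -1
  OXO:
    angles: []
    atoms:
    - O
    bonds: []
    charge: -2
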