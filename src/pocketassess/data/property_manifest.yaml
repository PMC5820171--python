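# Default microenvironment property manifest: 80 distance-only rules
# aggregated per shell. Rules are a function of atom/residue identity and
# scalar per-atom attributes only (never of absolute orientation), so any
# descriptor built from them is rigid-motion invariant.
# kind: count = number of qualifying atoms; sum = summed per-atom value;
# mean = summed value / atoms in shell (0 for empty shells).
properties:
- name: RES_ALA
  kind: count
  extractor: residue_is:ALA
- name: RES_ARG
  kind: count
  extractor: residue_is:ARG
- name: RES_ASN
  kind: count
  extractor: residue_is:ASN
- name: RES_ASP
  kind: count
  extractor: residue_is:ASP
- name: RES_CYS
  kind: count
  extractor: residue_is:CYS
- name: RES_GLN
  kind: count
  extractor: residue_is:GLN
- name: RES_GLU
  kind: count
  extractor: residue_is:GLU
- name: RES_GLY
  kind: count
  extractor: residue_is:GLY
- name: RES_HIS
  kind: count
  extractor: residue_is:HIS
- name: RES_ILE
  kind: count
  extractor: residue_is:ILE
- name: RES_LEU
  kind: count
  extractor: residue_is:LEU
- name: RES_LYS
  kind: count
  extractor: residue_is:LYS
- name: RES_MET
  kind: count
  extractor: residue_is:MET
- name: RES_PHE
  kind: count
  extractor: residue_is:PHE
- name: RES_PRO
  kind: count
  extractor: residue_is:PRO
- name: RES_SER
  kind: count
  extractor: residue_is:SER
- name: RES_THR
  kind: count
  extractor: residue_is:THR
- name: RES_TRP
  kind: count
  extractor: residue_is:TRP
- name: RES_TYR
  kind: count
  extractor: residue_is:TYR
- name: RES_VAL
  kind: count
  extractor: residue_is:VAL
- name: ELEM_C
  kind: count
  extractor: element_is:C
- name: ELEM_N
  kind: count
  extractor: element_is:N
- name: ELEM_O
  kind: count
  extractor: element_is:O
- name: ELEM_S
  kind: count
  extractor: element_is:S
- name: CHARGE_POSITIVE_ATOMS
  kind: count
  extractor: charge_class:positive
- name: CHARGE_NEGATIVE_ATOMS
  kind: count
  extractor: charge_class:negative
- name: CHARGE_NEUTRAL_ATOMS
  kind: count
  extractor: charge_class:neutral
- name: FORMAL_CHARGE_SUM
  kind: sum
  extractor: formal_charge
- name: KYTE_DOOLITTLE_SUM
  kind: sum
  extractor: kyte_doolittle_ca
- name: HBOND_DONOR
  kind: count
  extractor: hbond_donor
- name: HBOND_ACCEPTOR
  kind: count
  extractor: hbond_acceptor
- name: AROMATIC_RING_ATOMS
  kind: count
  extractor: aromatic_ring
- name: BACKBONE_ATOMS
  kind: count
  extractor: backbone
- name: SIDECHAIN_ATOMS
  kind: count
  extractor: sidechain
- name: BFACTOR_MEAN
  kind: mean
  extractor: bfactor
- name: OCCUPANCY_MEAN
  kind: mean
  extractor: occupancy
- name: CLASS_HYDROPHOBIC
  kind: count
  extractor: residue_class:hydrophobic
- name: CLASS_POLAR
  kind: count
  extractor: residue_class:polar
- name: CLASS_ACIDIC
  kind: count
  extractor: residue_class:acidic
- name: CLASS_BASIC
  kind: count
  extractor: residue_class:basic
- name: CLASS_AMIDE
  kind: count
  extractor: residue_class:amide
- name: CLASS_SULFUR
  kind: count
  extractor: residue_class:sulfur
- name: CLASS_SMALL
  kind: count
  extractor: residue_class:small
- name: CLASS_AROMATIC
  kind: count
  extractor: residue_class:aromatic
- name: FG_HYDROXYL
  kind: count
  extractor: functional_group:hydroxyl
- name: FG_CARBOXYLATE
  kind: count
  extractor: functional_group:carboxylate
- name: FG_AMIDE
  kind: count
  extractor: functional_group:amide
- name: FG_GUANIDINIUM
  kind: count
  extractor: functional_group:guanidinium
- name: FG_IMIDAZOLE
  kind: count
  extractor: functional_group:imidazole
- name: FG_THIOL_THIOETHER
  kind: count
  extractor: functional_group:thiol_thioether
- name: SS_HELIX_CA
  kind: count
  extractor: ss_ca:helix
- name: SS_EXTENDED_CA
  kind: count
  extractor: ss_ca:extended
- name: SS_OTHER_CA
  kind: count
  extractor: ss_ca:other
- name: ATOM_N
  kind: count
  extractor: atom_is:N
- name: ATOM_CA
  kind: count
  extractor: atom_is:CA
- name: ATOM_C
  kind: count
  extractor: atom_is:C
- name: ATOM_O
  kind: count
  extractor: atom_is:O
- name: ATOM_CB
  kind: count
  extractor: atom_is:CB
- name: ATOM_CG
  kind: count
  extractor: atom_is:CG
- name: ATOM_CG1
  kind: count
  extractor: atom_is:CG1
- name: ATOM_CG2
  kind: count
  extractor: atom_is:CG2
- name: ATOM_CD
  kind: count
  extractor: atom_is:CD
- name: ATOM_CD1
  kind: count
  extractor: atom_is:CD1
- name: ATOM_CD2
  kind: count
  extractor: atom_is:CD2
- name: ATOM_CE
  kind: count
  extractor: atom_is:CE
- name: ATOM_CE1
  kind: count
  extractor: atom_is:CE1
- name: ATOM_CE2
  kind: count
  extractor: atom_is:CE2
- name: ATOM_CZ
  kind: count
  extractor: atom_is:CZ
- name: ATOM_OG
  kind: count
  extractor: atom_is:OG
- name: ATOM_OG1
  kind: count
  extractor: atom_is:OG1
- name: ATOM_OH
  kind: count
  extractor: atom_is:OH
- name: ATOM_OD1
  kind: count
  extractor: atom_is:OD1
- name: ATOM_OD2
  kind: count
  extractor: atom_is:OD2
- name: ATOM_OE1
  kind: count
  extractor: atom_is:OE1
- name: ATOM_OE2
  kind: count
  extractor: atom_is:OE2
- name: ATOM_ND1
  kind: count
  extractor: atom_is:ND1
- name: ATOM_ND2
  kind: count
  extractor: atom_is:ND2
- name: ATOM_NE
  kind: count
  extractor: atom_is:NE
- name: ATOM_NE1
  kind: count
  extractor: atom_is:NE1
- name: ATOM_NE2
  kind: count
  extractor: atom_is:NE2
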