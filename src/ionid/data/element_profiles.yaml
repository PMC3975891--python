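# Per-element chemistry profiles for the supported candidate ions.
#
# donors: list of "ELEMENT:CONTEXT" pairs. CONTEXT is one of
#   any  - the donor element in any residue
#   CYS  - cysteine thiolate S (SG)
#   MET  - methionine thioether S (SD)
#   HIS  - histidine imidazole N (ND1/NE2)
#   LIG  - a non-polymer (hetero) residue other than water
# An "E:any" entry subsumes the specific contexts of element E.
#
# Thiolate coordination is restricted to Co, Fe, Ni, Zn and Cu; methionine
# coordination to Co, Ni and Cu. Na/K/Ca are oxygen-binders; Mg additionally
# accepts N donated by a ligand (e.g. the bridging N of AMP-PNP).
# Coordination-number ranges follow Harding's surveys of metal sites in
# proteins: Na 4-6, Mg 6, K 6-8, Ca 6-8, first-row transition metals 4-6,
# Cd 4-7. For chloride the "coordinating" contacts counted are positively
# polarized groups (amide/guanidinium/ammonium N, metal cations).
NA:
  formal_charge: 1
  atomic_number: 11
  weight_class: light
  donors: ["O:any"]
  coordination_range: [4, 6]
  required_geometry: any
MG:
  formal_charge: 2
  atomic_number: 12
  weight_class: light
  donors: ["O:any", "N:LIG"]
  coordination_range: [6, 6]
  required_geometry: octahedral
CL:
  formal_charge: -1
  atomic_number: 17
  weight_class: heavy
  donors: ["N:any"]
  coordination_range: [1, 6]
  required_geometry: any
K:
  formal_charge: 1
  atomic_number: 19
  weight_class: heavy
  donors: ["O:any"]
  coordination_range: [6, 8]
  required_geometry: any
CA:
  formal_charge: 2
  atomic_number: 20
  weight_class: heavy
  donors: ["O:any"]
  coordination_range: [6, 8]
  required_geometry: any
MN:
  formal_charge: 2
  atomic_number: 25
  weight_class: heavy
  donors: ["O:any", "N:any"]
  coordination_range: [4, 6]
  required_geometry: any
FE:
  formal_charge: 2
  atomic_number: 26
  weight_class: heavy
  donors: ["O:any", "N:any", "S:CYS"]
  coordination_range: [4, 6]
  required_geometry: any
CO:
  formal_charge: 2
  atomic_number: 27
  weight_class: heavy
  donors: ["O:any", "N:any", "S:CYS", "S:MET"]
  coordination_range: [4, 6]
  required_geometry: any
NI:
  formal_charge: 2
  atomic_number: 28
  weight_class: heavy
  donors: ["O:any", "N:any", "S:CYS", "S:MET"]
  coordination_range: [4, 6]
  required_geometry: any
CU:
  formal_charge: 2
  atomic_number: 29
  weight_class: heavy
  donors: ["O:any", "N:any", "S:CYS", "S:MET"]
  coordination_range: [4, 6]
  required_geometry: any
ZN:
  formal_charge: 2
  atomic_number: 30
  weight_class: heavy
  donors: ["O:any", "N:any", "S:CYS"]
  coordination_range: [4, 6]
  required_geometry: any
CD:
  formal_charge: 2
  atomic_number: 48
  weight_class: heavy
  donors: ["O:any", "N:any"]
  coordination_range: [4, 7]
  required_geometry: any
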