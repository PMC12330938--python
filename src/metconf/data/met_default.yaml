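# Default configuration: human MET receptor tyrosine kinase.
#
# All positions are long-isoform numbering (transcript variant 1,
# NM_001127500.1).  Most PDB depositions of the MET kinase domain use the
# short-isoform scheme, 18 residues behind (catalytic Lys K1128 -> K1110);
# candidate_offsets lets the resolver recognise either.

candidate_offsets: [0, -18]
model_index: 1

residue_specs:
  - {position: 1076, aa: L, label: "aJM-helix Leu"}
  - {position: 1080, aa: L, label: "aJM-helix Leu"}
  - {position: 1084, aa: V, label: "aJM-helix Val"}
  - {position: 1086, aa: H, label: "aJM-helix His, inactive-bridge donor"}
  - {position: 1102, aa: I, label: "beta1 Ile, ATP-site entrance"}
  - {position: 1112, aa: H, label: "beta2 His"}
  - {position: 1124, aa: H, label: "beta3 His"}
  - {position: 1128, aa: K, label: "catalytic Lys, active-bridge donor"}
  - {position: 1139, aa: V, label: "aC-helix Val"}
  - {position: 1143, aa: L, label: "aC-helix Leu"}
  - {position: 1145, aa: E, label: "aC-helix Glu, active-bridge acceptor"}
  - {position: 1147, aa: I, label: "aC-helix Ile"}
  - {position: 1151, aa: D, label: "aC-helix Asp, inactive-bridge acceptor"}
  - {position: 1176, aa: P, label: "hinge Pro"}
  - {position: 1178, aa: M, label: "hinge Met"}
  - {position: 1240, aa: D, label: "DFG Asp"}
  - {position: 1268, aa: M, label: "C-lobe Met"}

bridges:
  - name: HD
    label: "aJM-helix H1086 - aC-helix D1151 (inactive marker)"
    donor: {position: 1086, aa: H, atoms: [ND1, NE2]}
    acceptor: {position: 1151, aa: D, atoms: [OD1, OD2]}
    cutoff: 4.0
  - name: KE
    label: "beta3 K1128 - aC-helix E1145 (active marker)"
    donor: {position: 1128, aa: K, atoms: [NZ]}
    acceptor: {position: 1145, aa: E, atoms: [OE1, OE2]}
    cutoff: 4.0

contacts:
  - {a: {position: 1084, aa: V}, b: {position: 1147, aa: I}, cutoff: 4.5}
  - {a: {position: 1080, aa: L}, b: {position: 1143, aa: L}, cutoff: 4.5}
  - {a: {position: 1076, aa: L}, b: {position: 1139, aa: V}, cutoff: 4.5}

domains:
  - {name: "SEMA domain", start: 25, end: 515}
  - {name: "PSI domain", start: 516, end: 562}
  - {name: "IPT repeats", start: 563, end: 950}
  - {name: "Transmembrane", start: 951, end: 973}
  - {name: "Juxtamembrane domain", start: 974, end: 1070}
  - {name: "Kinase domain", start: 1071, end: 1363}
  - {name: "C-terminal tail", start: 1364, end: 1408}

kinase_sub_elements:
  - {name: "aJM-helix", start: 1071, end: 1086}
  - {name: "beta1 strand", start: 1097, end: 1104}
  - {name: "P-loop", start: 1105, end: 1110}
  - {name: "beta2-beta3", start: 1111, end: 1130}
  - {name: "aC-helix", start: 1135, end: 1152}
  - {name: "hinge", start: 1176, end: 1180}
  - {name: "catalytic loop", start: 1216, end: 1224}
  - {name: "activation loop", start: 1240, end: 1263}
  - {name: "C-lobe", start: 1264, end: 1363}
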