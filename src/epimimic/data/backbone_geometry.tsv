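# Ideal peptide backbone geometry used by the synthetic-structure builder.
# Bond lengths in Angstroms, angles in degrees (Engh & Huber-style standard values).
parameter	value
bond_N_CA	1.458
bond_CA_C	1.525
bond_C_N	1.329
bond_C_O	1.231
bond_CA_CB	1.521
angle_N_CA_C	111.2
angle_CA_C_N	116.2
angle_C_N_CA	121.7
angle_CA_C_O	120.8
angle_N_CA_CB	110.5
torsion_CB	123.0
omega	180.0
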