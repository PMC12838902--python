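# Published per-residue interaction distances for the ST8Sia4-LFcinB11 docking
# model (LFcinB11: 11-residue lactoferricin-derived peptide RRWQWRMKKLG).
# One row per listed interaction; 23 rows.
residue,distance_A,printed_class
K248,3.1,moderate_hbond
V251,3.0,moderate_hbond
A254,2.9,moderate_hbond
N247,3.7,weak_hbond_vdw
V251,4.0,weak_hbond_vdw
R252,3.6,weak_hbond_vdw
A254,3.9,weak_hbond_vdw
Y255,3.8,weak_hbond_vdw
N247,4.6,hydrophobic
K248,4.2,hydrophobic
K248,4.7,hydrophobic
L249,5.1,hydrophobic
K250,5.0,hydrophobic
K250,5.1,hydrophobic
R252,4.2,hydrophobic
R252,4.4,hydrophobic
R252,4.5,hydrophobic
R252,4.8,hydrophobic
R252,5.0,hydrophobic
R252,5.6,hydrophobic
T253,4.1,hydrophobic
T253,5.2,hydrophobic
Y255,4.2,hydrophobic
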