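# Published per-residue interaction distances for the ST8Sia4-LMWH docking model,
# as listed column-by-column in the interaction table (22 rows). The published
# totals are internally inconsistent (printed total 21, narrative total 20,
# narrative class counts 1/6/14); see fixtures_meta.json. Not used for acceptance
# totals, only as a sanity band on the recomputed mean.
residue,distance_A,printed_class
R252,2.4,moderate_hbond
A254,3.3,moderate_hbond
K248,3.6,weak_hbond_vdw
K248,3.8,weak_hbond_vdw
L249,3.9,weak_hbond_vdw
V251,3.8,weak_hbond_vdw
R252,3.9,weak_hbond_vdw
N247,4.7,hydrophobic
K248,4.3,hydrophobic
L249,4.1,hydrophobic
L249,4.5,hydrophobic
L249,4.8,hydrophobic
K250,4.3,hydrophobic
V251,4.8,hydrophobic
R252,4.2,hydrophobic
R252,4.8,hydrophobic
R252,4.8,hydrophobic
R252,5.1,hydrophobic
R252,6.0,hydrophobic
T253,4.7,hydrophobic
T253,4.7,hydrophobic
Y255,4.4,hydrophobic
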