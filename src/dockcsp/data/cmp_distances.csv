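# Published per-residue interaction distances for the ST8Sia4-CMP docking model.
# One row per listed receptor-residue <-> ligand-atom interaction ("binding site").
# printed_class records the distance-class column the value was printed under.
residue,distance_A,printed_class
L249,3.2,moderate_hbond
A254,2.9,moderate_hbond
K248,3.6,weak_hbond_vdw
L249,3.9,weak_hbond_vdw
K250,3.9,weak_hbond_vdw
V251,3.9,weak_hbond_vdw
N247,4.3,hydrophobic
N247,5.0,hydrophobic
K248,5.1,hydrophobic
V251,4.3,hydrophobic
R252,4.5,hydrophobic
R252,5.0,hydrophobic
R252,6.1,hydrophobic
R252,6.9,hydrophobic
T253,5.1,hydrophobic
A254,4.9,hydrophobic
Y255,4.8,hydrophobic
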