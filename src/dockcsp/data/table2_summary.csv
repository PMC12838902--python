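# Published docking-vs-NMR comparison summary for the three ST8Sia4 ligands:
# binding residue range of the docking model, largest-CSP range and peak from
# the HSQC titrations, hotspot residue with its docking contact count, and
# titration ligand concentration (molar).
ligand,docking_range,csp_range,hotspot_residue,hotspot_sites,peak_csp_ppm,concentration_M
CMP,N247-Y255,N247-Y255,R252,4,0.087,1e-3
LMWH,N247-Y255,N247-Y255,R252,6,0.087,80e-6
LFcinB11,N247-Y255,N247-Y255,R252,7,0.151,60e-6
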