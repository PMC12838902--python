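{
  "cmp": {
    "rows": 17,
    "class_counts": {"moderate_hbond": 2, "weak_hbond_vdw": 4, "hydrophobic": 11},
    "printed_total_sites": 17,
    "printed_mean_A": 4.55,
    "recomputed_mean_A": 4.5529,
    "internally_inconsistent": false,
    "notes": "Printed total and mean agree with the printed distance list."
  },
  "lmwh": {
    "rows": 22,
    "table_class_counts": {"moderate_hbond": 2, "weak_hbond_vdw": 5, "hydrophobic": 15},
    "narrative_class_counts": {"moderate_hbond": 1, "weak_hbond_vdw": 6, "hydrophobic": 14},
    "printed_total_sites_table": 21,
    "printed_total_sites_narrative": 20,
    "printed_mean_A": 4.33,
    "recomputed_mean_A": 4.3136,
    "hotspot_sites_summary": 6,
    "hotspot_sites_from_table": 7,
    "internally_inconsistent": true,
    "notes": "The interaction table lists 22 distances but prints total 21; the narrative counts 1 moderate / 6 weak / 14 hydrophobic (total 20). The comparison summary credits R252 with 6 sites while the table's R252 entries (2.4 moderate + 3.9 weak + five hydrophobic) sum to 7. LMWH totals are excluded from acceptance; only the recomputed table mean is sanity-banded."
  },
  "lfcinb11": {
    "rows": 23,
    "class_counts": {"moderate_hbond": 3, "weak_hbond_vdw": 5, "hydrophobic": 15},
    "printed_total_sites_table": 23,
    "printed_total_sites_narrative": 24,
    "printed_mean_A": 4.23,
    "recomputed_mean_A": 4.2913,
    "internally_inconsistent": true,
    "notes": "Narrative total (24) disagrees with the 23 listed distances; the printed mean 4.23 does not equal the mean of the listed distances (4.29)."
  },
  "lfcinb11_concentration_M": {
    "primary": 6e-05,
    "alternative": 8e-05,
    "notes": "The titration concentration is reported as 60 uM alongside the quantitative CSP curves and as 80 uM elsewhere; the curve-linked value is primary."
  },
  "concentrations_M": {"CMP": 0.001, "LMWH": 8e-05, "LFcinB11": 6e-05},
  "excluded_from_acceptance": [
    "LMWH total sites (printed 20 and 21 vs 22 listed distances)",
    "printed means 4.33 (LMWH) and 4.23 (LFcinB11), inconsistent with their distance lists"
  ]
}
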