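protein_id	category
CD9	tetraspanin
CD63	tetraspanin
CD81	tetraspanin
ALIX	cytosolic_marker
PDCD6IP	cytosolic_marker
TSG101	cytosolic_marker
SDCBP	cytosolic_marker
syntenin-1	cytosolic_marker
FLOT1	cytosolic_marker
flotillin-1	cytosolic_marker
ANXA5	annexin
ANXA7	annexin
ALB	contaminant
serum albumin	contaminant
HSP90B1	contaminant
endoplasmin	contaminant
CYC1	expected_absent
cytochrome C1	expected_absent
HLA-A	expected_absent
CANX	expected_absent
calnexin	expected_absent
APOA2	expected_absent
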