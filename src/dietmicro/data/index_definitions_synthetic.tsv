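index	subgroup_id	weight
EDIH	3	0.06
EDIH	12	0.035
EDIH	27	0.028
EDIH	45	0.022
EDIH	51	0.018
EDIH	88	0.015
EDIH	101	0.012
EDIH	169	0.025
EDIH	116	0.01
EDIH	7	-0.045
EDIH	19	-0.03
EDIH	33	-0.024
EDIH	60	-0.02
EDIH	72	-0.016
EDIH	95	-0.013
EDIH	110	-0.011
EDIH	124	-0.008
EDIH	170	-0.014
EDIP	3	0.04
EDIP	27	0.03
EDIP	45	0.018
EDIP	169	0.032
EDIP	55	0.02
EDIP	83	0.012
EDIP	120	0.009
EDIP	7	-0.035
EDIP	19	-0.022
EDIP	60	-0.015
EDIP	95	-0.012
EDIP	14	-0.018
EDIP	66	-0.01
EDIP	105	-0.008
EDIP	170	-0.011
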