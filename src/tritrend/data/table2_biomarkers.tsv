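protein_id	fc_LH	sig_LH	fc_NLH	sig_NLH	fc_NLL	sig_NLL
AKR1B10	32.769	1	25.318	0	0.773	0
CSTA	2.335	1	1.752	0	0.75	0
FABP5	15.076	1	4.678	0	0.31	1
PI3	52.616	1	4.105	0	0.078	0
S100A2	5.878	1	2.527	0	0.43	0
S100A7	14.74	1	7.519	0	0.51	0
S100A8	20.639	1	5.234	0	0.254	1
S100A9	19.679	1	3.306	0	0.168	1
SCCA2	35.468	1	9.221	0	0.26	1
STAT1	20.504	1	14.478	0	0.706	0
STAT3	3.766	1	2.309	0	0.613	0
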