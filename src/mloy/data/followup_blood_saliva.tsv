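sample_id	baseline_blood_pct	followup_blood_pct	saliva_pct
V15429	27	30	ND
V16554	52	67	57
V16763	41	50	ND
V19232	41	53	ND
V22330	52	46	ND
V23235	37	48	27
V26736	42	49	ND
V31014	46	48	30
V31220	29	39	17
V32199	30	40	ND
V32632	46	82	ND
V32752	32	35	ND
V32850	33	43	ND
V34568	37	44	ND
V37288	31	44	ND
V40611	52	29	32
V44342	35	37	20
V47558	37	39	18
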