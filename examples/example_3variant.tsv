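snp	beta_E1	se_E1	beta_E2	se_E2	beta_out	se_out
rs1	0.10	0.01	0.05	0.01	0.050	0.005
rs2	0.08	0.01	0.07	0.01	0.052	0.005
rs3	0.12	0.01	0.04	0.01	0.052	0.005
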