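metric	value
total_preprocessed_reads	79944976
mapped_reads	67401008
pooled_pct_mirna	50
pooled_pct_yrna	38
pooled_pct_trna	10
case_pct_mirna	66.4
case_pct_trna	3.0
case_pct_yrna	30.2
control_pct_mirna	39.6
control_pct_trna	15.6
control_pct_yrna	44.2
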