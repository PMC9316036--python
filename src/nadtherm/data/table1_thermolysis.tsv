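compound	temperature_C	rate_pct_per_min	sd_pct_per_min
NR	50	0.68	0.04
NR	75	2.06	0.10
NR	90	6.26	0.07
NMN	50	0.07	0.02
NMN	75	0.62	0.03
NMN	90	2.76	0.13
NAD	50	0.00	0.01
NAD	75	0.45	0.01
NAD	90	1.60	0.05
NAR	50	0.01	0.01
NAR	75	0.12	0.02
NAR	90	0.86	0.02
NAMN	50	0.00	0.01
NAMN	75	0.05	0.03
NAMN	90	0.40	0.01
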