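site	latitude	longitude_w	pct_nitrogen	pct_carbon	salinity	air_temp
WB	41.580	70.521	0.92	13.85	25.1	17.1
PI	41.625	71.324	1.34	23.58	26.6	17.8
JR	39.089	75.437	0.52	5.99	10.7	20.1
RC	34.723	76.675	0.57	8.78	32.3	23.0
AB	32.558	80.439	0.51	8.59	26.4	24.2
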