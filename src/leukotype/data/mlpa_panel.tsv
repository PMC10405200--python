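gene	probe	chrom	pos
EBF1	1	chr5	800000
EBF1	2	chr5	897500
EBF1	3	chr5	995000
EBF1	4	chr5	1092500
EBF1	5	chr5	1190000
IKZF1	1	chr7	200000
IKZF1	2	chr7	220000
IKZF1	3	chr7	240000
IKZF1	4	chr7	260000
IKZF1	5	chr7	280000
IKZF1	6	chr7	300000
CDKN2A	1	chr9	400000
CDKN2A	2	chr9	410000
CDKN2A	3	chr9	420000
CDKN2A	4	chr9	430000
CDKN2B	1	chr9	440000
CDKN2B	2	chr9	445000
CDKN2B	3	chr9	450000
PAX5	1	chr9	700000
PAX5	2	chr9	740000
PAX5	3	chr9	780000
PAX5	4	chr9	820000
PAX5	5	chr9	860000
PAX5	6	chr9	900000
ETV6	1	chr12	500000
ETV6	2	chr12	562500
ETV6	3	chr12	625000
ETV6	4	chr12	687500
ETV6	5	chr12	750000
BTG1	1	chr12	1100000
BTG1	2	chr12	1105000
BTG1	3	chr12	1110000
RB1	1	chr13	800000
RB1	2	chr13	845000
RB1	3	chr13	890000
RB1	4	chr13	935000
RB1	5	chr13	980000
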