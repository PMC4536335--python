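sample	cellularity	intensity	score
A2008	2	2	4
A2780CP	0	0	0
A2780S	1	1	1
BGI	0	0	0
C13	3	1	3
CAOV3	3	1	3
CHI	0	0	0
CHI cisR	1	1	1
CAOV2	3	2	6
Dov 13	3	2	6
HeyA8	3	1	3
IGR-OV1	3	2	6
IMCC3	2	1	2
IMCC5	1	1	1
M41	1	1	1
M41CSR	2	1	2
MCAS	3	1	3
OV2008	1	1	1
OV90	1	1	1
Ovary1847	1	1	1
OVCA 429	2	1	2
OVCA 432	Acellular	n/a	n/a
OVCA 433	3	1	3
OVCA420	1	2	2
OVCAR10	0	0	0
OVCAR2	3	2	6
OVCAR3	2	1	2
OVCAR4	3	2	6
OVCAR5	3	2	6
OVCAR8	3	1	3
PEO1	3	2	6
PEO4	2	2	4
SKOV8	2	1	2
SKOV3	3	2	6
SKOV4	0	0	0
SKOV6	2	1	2
T8	3	2	6
Tov-112D	2	1	2
Tov-21-G	1	1	1
Tyknu	0	0	0
Tyknu CisR	0	0	0
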