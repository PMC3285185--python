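locus	length_bp	pi	phi_st	tajd
CHD1Z	270	0.0015	0.038	-0.67
LDHB	461	0.0008	0.143	-0.96
CD4	345	0.0010	-0.002	-2.14
FAST	322	0.0027	0.026	-1.13
ODC1	295	0.0143	0.010	-0.66
FGB	433	0.0076	0.032	-0.61
SAA	351	0.0195	0.053	-0.22
ANXA11	405	0.0061	0.132	-0.41
MSTN	291	0.0175	0.026	-0.20
SOAT1	352	0.0071	-0.014	0.72
NCL	341	0.0260	0.068	0.69
LCAT	339	0.0215	0.036	0.66
GHRL	351	0.0220	0.191	0.10
GRIN1	290	0.0004	0.014	-1.28
SOX9	381	0.0295	0.045	-0.04
CPD	328	0.0293	0.092	1.11
PCK1	325	0.0036	0.001	0.43
ENO1	175	0.0062	0.089	-1.03
CRYAB	294	0.0015	0.147	-0.14
GH1	363	0.0018	0.005	-0.33
Sf3A2	305	0.0004	0.007	-1.43
A27E1	183	0.0027	0.292	-0.67
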