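gene	lung	lung_injury	acute_lung_injury
IL1R2	11	3	1
IL1B	59	11	4
CLEC4D	1	1	0
CD300LF	0	0	0
CLEC4E	1	0	0
PAI1	548	159	91
LILRB4	4	0	0
S100A9	88	8	2
CCR1	84	10	6
CXCL2	600	250	134
IL6	3325	52	4
PLAUR	146	16	6
CCRN4L	0	0	0
CH25H	3	0	0
NFIL3	2	1	1
S100A8	96	12	6
MMP8	20	5	4
SOCS3	82	15	8
BCL3	2	1	1
MAFF	3	0	0
THBS1	140	12	1
RHOU	3	0	0
CXCL3	13	3	2
GADD45G	10	0	0
SPHK1	32	6	0
SAMSN1	3	0	0
ZFP36	11	0	0
CXCL1	458	163	91
CDKN1A	714	35	5
ARG2	23	1	0
CCL3	305	54	26
JUNB	55	3	0
PLA2G7	2	0	0
ARID5A	0	0	0
SLPI	184	28	10
APOLD1	1	0	0
CSF2RB	18	1	0
FPR2	42	6	4
ADM	440	21	8
OSMR	7	0	0
TREM1	39	21	3
TNFAIP3	16	5	3
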