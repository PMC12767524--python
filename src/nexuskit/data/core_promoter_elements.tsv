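Name	Sequence	Start window	End window
TATA	STATAWAWR	-40	-20
INR	TCAKTY	-5	5
DPE	GGWYV	25	35
MTE	CSARCSSA	10	30
PB	KCGRWCG	20	50
DRE	WATCGATW	-70	-10
Ohler1	GGTCACACTR	-10	10
Ohler6	RGTATWTT	-50	-10
Ohler7	CAKCNCTR	-70	10
TCT	YYCTTTYY	-10	10
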