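node	initial	desired
CD45	1	1
CD4	0	0
TCRbind	0	1
TCRlig	1	1
PAGCsk	0	1
cCbl	0	0
NFAT	0	0
Fyn	0	1
Lck	1	0
Calcin	0	0
TCRphos	0	1
Rlk	0	0
ZAP-70	0	0
Caplus	0	0
LATphop	0	0
Gads	0	0
IP3	0	0
SLP76	0	0
Itk	0	0
PLCgact	1	0
Grb2Sas	0	0
PLCgbind	0	0
DAG	0	0
Ras	0	0
RasGRP1	0	0
PKCth	1	1
CRE	0	0
Raf	0	0
SEK	0	1
IKKbeta	0	1
CREB	1	0
MEK	0	1
AP1	0	0
JNK	0	1
IKB	1	0
Rsk	0	0
ERK	0	0
Fos	1	0
JUN	0	1
NFkB	0	1
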