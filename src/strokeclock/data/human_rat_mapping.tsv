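external	internal	kind
ACSL1	Acsl1	homolog
ADM	Adm	homolog
APLP2	Aplp2	homolog
ARG1	Arg1	homolog
BCL6	Bcl6	homolog
NPPB	Nppb	homolog
BST1	Bst1	homolog
MCEMP1	Mcemp1	homolog
C3AR1	C3ar1	homolog
CA4	Car4	homolog
CCR7	Ccr7	homolog
CD14-1	Cd14	homolog
CD163	Cd163	homolog
CD93	Cd93	homolog
CKAP4	Ckap4	homolog
CRP	Crp	homolog
CYBB	Cybb	homolog
PARK7	Park7	homolog
DUSP1	Dusp1	homolog
ENTPD1	Entpd1	homolog
ETS2	Ets2	homolog
F5	F5	homolog
FCGR1A	Fcgr1a	homolog
FOS	Fos	homolog
FPR1	Fpr1	homolog
FPR2	Fpr2	homolog
GFAP	Gfap	homolog
GSTP1	Gstp1	homolog
IL13RA1	Il13ra1	homolog
IL18R1	Il18r1	homolog
IL18RAP	Il18rap	homolog
IL1R2	Il1r2	homolog
IL1RN	Il1rn	homolog
IL6	Il6	homolog
IQGAP1	Iqgap1	homolog
SPIDR	Spidr	homolog
LTA4H	Lta4h	homolog
MBP	Mbp	homolog
MGAM	Mgam	homolog
MMP9	Mmp9	homolog
NME1	Nme1	homolog
NKG7	Nkg7	homolog
NPL	Npl	homolog
ENO2	Eno2	homolog
ORM1	Orm1	homolog
SELP	Selp	homolog
PDE4D	Pde4d	homolog
PILRA	Pilra	homolog
PLBD1	Plbd1	homolog
PYGL	Pygl	homolog
RNASE2	Rnase2	homolog
S100A9	S100a9	homolog
S100B	S100b	homolog
SDPR	Sdpr	homolog
SLC16A6	Slc16a6	homolog
TLR2	Tlr2	homolog
Vcam1	Vcam1	homolog
VCAN	Vcan	homolog
VWF	Vwf	homolog
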