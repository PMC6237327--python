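name,alt_name,source,note
ACSL1,,7,
ADM,,1;6,
APLP2,,1,
ARG1,,2;3,
BCL6,,2,
BNP,NPPB,11,
BST1,,1;6,
C19orf59,MCEMP1,7,
C3AR1,,4,
CA4,,2;3,
CCR7,,3,
CD14-1,,1,
CD163,,1,
CD36,,1,not_on_array
CD93,,1;6,
CKAP4,,2;6,
CRP,,10;11,
CSPG2,,3,not_on_array
CYBB,,1;6,
Ddimer,,11,protein_dimer
DJ1,PARK7,12,
DUSP1,,1,
ENTPD1,,1,
EOMES,,7,not_on_array
ETS2,,1;2,
F5-1,F5,2,
FCGR1A,,1,
FOS,,1,
FPR1,,2,
FPRL1,FPR2,4,
GFAP,,9;10,
GNLY,,7,not_on_array
GST-pi,GSTP1,12,
HIST2H2AA3,,2,not_on_array
homocystein,,10,metabolite
HOX 1.11,HOXA2,2,not_on_array
IL13RA1,,1,
IL18R1,,7,
IL18RAP,,7,
IL1R2,,7,
IL1RN,,4,
IL6,,12,
IL8,,8,not_on_array
IQGAP1,,3,
KIAA0146,SPIDR,1,
LOC642103,,7,discontinued
LTA4H,,1,
LY96,,2;3;8,not_on_array
MBP,,9,
MGAM,,7,
MMP9,,2;3;5;7;11,
NAIP,Naip6,1,not_on_array
NDKA,NME1,12,
NKG7,,7,
NPL,,1;2,
NSE,ENO2,9,
Nt-proBNP,NPPB,12,
ORM1,,3,
P selectin,SELP,10,
PDE4D,,4,
PILRA,,1,
PLBD1,,1;6,
PYGL,,2;6,
RNASE2,,2,
S100A12,,2;3;6,not_on_array
S100A9,,2;6,
S100B,,5;9,
S100P,,2,not_on_array
SDPR,,8,
SLC16A6,,2,
TLR2,,1,
VCAM,Vcam1,5,
VCAN,,1,
VonWillebrand factor,VWF,5,
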