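protein	tw_vs_ew	tf_vs_tw
EXOC8	down	up
NRXN1	down	up
PARK7	down	up
AP2A1	down	up
AP2A2	down	up
AP2B1	down	up
SNAP91	down	up
DMXL2	down	up
CLTA	down	up
CLTB	down	up
CLTC	down	up
OCRL	down	up
SCYL2	down	up
EXOC1	down	up
EXOC3	down	up
HIP1	down	up
ITSN1	down	up
YWHAG	down	up
SACM1L	down	up
RPSA	down	up
RPS21	down	up
RPS28	down	up
EIF3C	down	up
EIF3E	down	up
EIF3H	down	up
EIF3I	down	up
EIF3L	down	up
PYCR1	down	up
NAXD	down	up
ECHS1	down	up
ARMC1	down	up
COMMD2	down	up
COMMD9	down	up
ZRANB2	down	up
GMFB	down	up
SPTBN2	up	down
EIF2S3X	up	down
TPD52L2	up	down
MINK1	up	down
TUBB2B	up	down
SPTAN1	up	down
ACTG1	up	down
RAB5B	up	down
MLF2	up	down
SLC25A22	up	down
CC2D1A	up	down
UBE3A	up	down
MYO5A	up	down
GRIN2A	up	down
DBN1	up	down
NEBL	up	down
MYO1B	up	down
GOLGA3	up	down
SPTBN3	up	down
PSMD3	up	down
SUCLG1	up	down
MTPAP	up	down
SFXN3	up	down
SFXN5	up	down
SLC25A11	up	down
NDUFA4	up	down
AIFM3	up	down
FECH	up	down
TIMM8B	up	down
ACAA2	up	down
ATP5C1	up	down
BCKDK	up	down
ANK2	up	down
NUDT16	up	down
MYO1D	up	down
LMTK3	up	down
PLEC	up	down
FMR1	up	down
WDFY3	up	down
UBE2M	up	down
PRRC2C	up	down
FLII	up	down
DIS3L2	up	down
LRRC73	up	down
ISCA2	up	down
SIK3	up	down
OLFM3	up	down
PPM1H	up	down
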