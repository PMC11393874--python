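# Frozen snapshot of a human DNA-repair gene symbol list, bundled for
# reproducibility (the upstream curated list is a living webpage).
# Symbols current per HGNC at the time of freezing; see panel_aliases.tsv
# for outdated symbols mapped onto this panel.
APEX1
APEX2
ATM
ATR
BARD1
BLM
BRCA1
BRCA2
BRIP1
CHEK1
CHEK2
DCLRE1A
DCLRE1B
DCLRE1C
EME1
ERCC1
ERCC2
ERCC3
ERCC4
ERCC5
ERCC6
ERCC8
EXO1
EXO5
FAAP100
FAAP24
FAN1
FANCA
FANCB
FANCC
FANCD2
FANCE
FANCF
FANCG
FANCI
FANCL
FANCM
FEN1
GTF2H1
GTF2H2
GTF2H3
GTF2H4
GTF2H5
HELQ
LIG1
LIG3
LIG4
MBD4
MGMT
MLH1
MLH3
MPG
MRE11
MSH2
MSH3
MSH4
MSH5
MSH6
MUTYH
NBN
NEIL1
NEIL2
NEIL3
NTHL1
OGG1
PALB2
PARP1
PER1
PMS1
PMS2
PNKP
POLB
POLD1
POLE
POLG
POLH
POLI
POLK
POLL
POLM
POLN
POLQ
PRKDC
RAD18
RAD23A
RAD23B
RAD50
RAD51
RAD51B
RAD51C
RAD51D
RAD52
RAD54B
RAD54L
RECQL
RECQL4
RECQL5
REV1
REV3L
RNF168
RNF4
RNF8
RPA1
RPA2
RPA3
SMUG1
SPIDR
TDG
TDP1
TOP3A
TOP3B
TP53
TP53BP1
TREX1
TREX2
UNG
WRN
XAB2
XPA
XPC
XRCC1
XRCC2
XRCC3
XRCC4
XRCC5
XRCC6
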