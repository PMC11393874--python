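MRE11A	MRE11
C17orf70	FAAP100
C19orf40	FAAP24
SHFM1	SEM1
BRE	BABAM2
WHSC1	NSD2
H2AFX	H2AX
RAD51L1	RAD51B
RAD51L3	RAD51D
SNM1	DCLRE1A
KIAA0146	SPIDR
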