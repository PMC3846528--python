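# organism	kind	partner  (SHT<->TPE pairings reciprocal; RT unpaired)
organism	kind	partner
A_deanei	SHT	K_crithidii
A_desouzai	SHT	K_desouzaii
S_culicis	SHT	K_blastocrithidii
S_oncopelti	SHT	K_oncopeltii
S_galati	SHT	K_galatii
K_crithidii	TPE	A_deanei
K_desouzaii	TPE	A_desouzai
K_blastocrithidii	TPE	S_culicis
K_oncopeltii	TPE	S_oncopelti
K_galatii	TPE	S_galati
H_muscarum	RT
C_acanthocephali	RT
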