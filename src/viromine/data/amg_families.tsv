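pfam_family	amg_category
NorD	N
NorQ_MoxR	N
Nitrate_red_del	N
Nitroreductase	N
NirB	N
Amidase	N
Glutaminase	N
CysD	S
CysH	S
PAPS_reduct	S
Sulfatase	S
Sulfotransfer_1	S
Thioredoxin	S
ALDH	pesticide
Aldedh	pesticide
HAD	pesticide
HAD_2	pesticide
Hydrolase	pesticide
Hydrolase_3	pesticide
Dehalogenase	pesticide
Haloacid_dh	pesticide
DLH	pesticide
Ring_hydroxyl_A	pesticide
Catalase	pesticide
GH1	C
GH3	C
GH5	C
GH13	C
GH16	C
GH18	C
GT2	C
GT4	C
GT35	C
CBM6	C
CBM13	C
CBM50	C
CE1	C
CE4	C
PL1	C
Glyco_hydro_2	C
Glyco_transf_20	C
Phosphodiest	P
PhoD	P
Phosphoesterase	P
Acid_phosphat_A	P
PhoH	P
PPK2	P
Phytase	P
Fer4	other
Cupin_2	other
2OG-FeII_Oxy	other
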