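# Transcription of the published xylanolytic-CAZyme table for the 12 top
# xylan-growing yeasts from the 332-genome budding-yeast dataset.
# Cells use copy notation: FAMILY(k), an absent parenthesis meaning one copy.
# printed_total is the Total column as printed; unique_families lists the
# families typeset in bold (unique to that species dataset-wide).
# Two printed totals disagree with the sum of their printed entries by one
# (Sc. stipitis, B. raffinosifermentans); both readings are preserved here
# and flagged, not silently corrected.
clade	species	CE	GH3	GH5	GH10	GH11	GH30	GH43	GH51	GH62	GH67	GH115	printed_total	unique_families
Trichomonascaceae	Sp. europaea	CE1, CE4, CE15	GH3(11)	GH5_5(2), GH5_9(2), GH5_12(2), GH5_22(4), GH5_49	GH10(2)		GH30_5, GH30_7	GH43_14, GH43_24	GH51		GH67	GH115(3)	36	
Trichomonascaceae	Su. lignohabitans	CE1(2), CE4(3), CE15	GH3(5)	GH5_9(2), GH5_12(2), GH5_22(2), GH5_49	GH10(2)		GH30_7		GH51			GH115	23	
Trichomonascaceae	B. peoriensis	CE1, CE4	GH3(15)	GH5_9(3), GH5_12(2), GH5_22(5), GH5_49	GH10		GH30_3(3)		GH51				33	
Trichomonascaceae	B. mokoenaii	CE1, CE4	GH3(8)	GH5, GH5_5, GH5_7(2), GH5_9(2), GH5_12, GH5_22(2), GH5_49		GH11	GH30_5, GH30_7	GH43_6, GH43_24	GH51(3)	GH62	GH67	GH115(2)	32	GH5_7,GH11,GH62
Trichomonascaceae	B. adeninivorans	CE1, CE4(2)	GH3(8)	GH5_9(3), GH5_12(2), GH5_44, GH5_47			GH30_3	GH43_6	GH51		GH67		22	
Trichomonascaceae	B. proliferans	CE1(2), CE4	GH3(12)	GH5_5(3), GH5_9(2), GH5_12, GH5_31, GH5_49			GH30_3		GH51(3)				27	
Trichomonascaceae	B. serpentis	CE1, CE4	GH3(5)	GH5, GH5_9(3), GH5_12, GH5_22, GH5_49			GH30_3(2)		GH51(2)				18	
Trichomonascaceae	B. raffinosifermentans	CE1, CE4(2), CE5(6)	GH3(9)	GH5_9(3), GH5_12(2), GH5_49			GH30_3	GH43_6	GH51		GH67		27	
CUG-Ser1	Spa. passalidarum	CE1, CE4(2)	GH3(9)	GH5, GH5_9(3), GH5_22, GH5_49								GH115	19	
CUG-Ser1	Sc. lignosus	CE1, CE4	GH3(7)	GH5_5, GH5_9(3), GH5_12, GH5_22(2), GH5_49	GH10(2)							GH115	20	
CUG-Ser1	Sc. stipitis	CE1, CE4	GH3(7)	GH5_9(2), GH5_12, GH5_22(3), GH5_49	GH10							GH115	17	
Phaffomycetaceae	W. canadensis	CE1(3), CE4	GH3(5)	GH5_9(2), GH5_12, GH5_22, GH5_49									14	
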