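parcel_name	hemisphere	network	vertex_count
LH_Vis	LH	Vis	1213
RH_Vis	RH	Vis	1264
LH_SomMot	LH	SomMot	1590
RH_SomMot	RH	SomMot	1612
LH_DorsAttn_Post	LH	DorsAttn	627
RH_DorsAttn_Post	RH	DorsAttn	614
LH_DorsAttn_FEF	LH	DorsAttn	97
RH_DorsAttn_FEF	RH	DorsAttn	98
LH_SalVentAttn_ParOper	LH	SalVentAttn	130
RH_DorsAttn_PrCv	RH	DorsAttn	50
LH_SalVentAttn_FrOper	LH	SalVentAttn	331
RH_SalVentAttn_TempOccPar	RH	SalVentAttn	208
LH_SalVentAttn_Med	LH	SalVentAttn	216
RH_SalVentAttn_FrOper	RH	SalVentAttn	313
LH_Limbic_OFC	LH	Limbic	213
RH_SalVentAttn_Med	RH	SalVentAttn	242
LH_Limbic_TempPole	LH	Limbic	328
RH_Limbic_OFC	RH	Limbic	237
LH_Cont_Par	LH	Cont	151
RH_Limbic_TempPole	RH	Limbic	318
LH_Cont_PFCl	LH	Cont	291
RH_Cont_Par	RH	Cont	167
LH_Default_Par	LH	Default	263
RH_Cont_PFCl	RH	Cont	543
LH_Default_Temp	LH	Default	359
RH_Default_Par	RH	Default	183
LH_Default_PFC	LH	Default	771
RH_Default_Temp	RH	Default	269
LH_Default_PCC	LH	Default	275
RH_Default_PFCv	RH	Default	60
RH_Default_PFCm	RH	Default	461
RH_Default_PCC	RH	Default	225
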