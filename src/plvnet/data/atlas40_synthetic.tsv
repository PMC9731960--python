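roi_name	network	hemisphere
Cingulate_Post L	DMN	L
Cingulate_Post R	DMN	R
Precuneus L	DMN	L
Frontal_Sup_Medial L	DMN	L
Frontal_Sup_Medial R	DMN	R
Frontal_Med_Orb L	DMN	L
Frontal_Med_Orb R	DMN	R
ParaHippocampal L	DMN	L
ParaHippocampal R	DMN	R
Temporal_Mid L	DMN	L
Temporal_Mid R	DMN	R
Parietal_Inf L	DMN	L
Parietal_Inf R	DMN	R
Frontal_Sup L	FPN	L
Frontal_Sup R	FPN	R
Frontal_Mid L	FPN	L
Frontal_Mid R	FPN	R
Thalamus L	FPN	L
Thalamus R	FPN	R
Parietal_Sup L	FPN	L
Parietal_Sup R	FPN	R
Paracentral_Lobule L	SMN	L
Paracentral_Lobule R	SMN	R
Postcentral L	SMN	L
Postcentral R	SMN	R
Precentral L	SMN	L
Precentral R	SMN	R
Supp_Motor_Area L	SMN	L
Cingulate_Mid L	CON	L
Cingulate_Mid R	CON	R
Frontal_Inf_Oper L	CON	L
Frontal_Inf_Oper R	CON	R
Rolandic_Oper L	CON	L
Rolandic_Oper R	CON	R
Cingulate_Ant L	SN	L
Cingulate_Ant R	SN	R
Insula L	SN	L
Insula R	SN	R
Supramarginal L	SN	L
Supramarginal R	SN	R
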