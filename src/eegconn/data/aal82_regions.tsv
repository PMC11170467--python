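name	abbreviation	hemisphere	lobe
Precentral gyrus (L)	PreCG.L	L	F
Precentral gyrus (R)	PreCG.R	R	F
Superior frontal gyrus, dorsolateral (L)	SFGdor.L	L	F
Superior frontal gyrus, dorsolateral (R)	SFGdor.R	R	F
Superior frontal gyrus, orbital part (L)	ORBsup.L	L	F
Superior frontal gyrus, orbital part (R)	ORBsup.R	R	F
Middle frontal gyrus (L)	MFG.L	L	F
Middle frontal gyrus (R)	MFG.R	R	F
Middle frontal gyrus, orbital part (L)	ORBmid.L	L	F
Middle frontal gyrus, orbital part (R)	ORBmid.R	R	F
Inferior frontal gyrus, opercular part (L)	IFGoperc.L	L	F
Inferior frontal gyrus, opercular part (R)	IFGoperc.R	R	F
Inferior frontal gyrus, triangular part (L)	IFGtriang.L	L	F
Inferior frontal gyrus, triangular part (R)	IFGtriang.R	R	F
Inferior frontal gyrus, orbital part (L)	ORBinf.L	L	F
Inferior frontal gyrus, orbital part (R)	ORBinf.R	R	F
Rolandic operculum (L)	ROL.L	L	F
Rolandic operculum (R)	ROL.R	R	F
Supplementary motor area (L)	SMA.L	L	F
Supplementary motor area (R)	SMA.R	R	F
Olfactory cortex (L)	OLF.L	L	F
Olfactory cortex (R)	OLF.R	R	F
Superior frontal gyrus, medial (L)	SFGmed.L	L	F
Superior frontal gyrus, medial (R)	SFGmed.R	R	F
Superior frontal gyrus, medial orbital (L)	ORBsupmed.L	L	F
Superior frontal gyrus, medial orbital (R)	ORBsupmed.R	R	F
Gyrus rectus (L)	REC.L	L	F
Gyrus rectus (R)	REC.R	R	F
Insula (L)	INS.L	L	L
Insula (R)	INS.R	R	L
Anterior cingulate gyrus (L)	ACG.L	L	L
Anterior cingulate gyrus (R)	ACG.R	R	L
Middle cingulate gyrus (L)	MCG.L	L	L
Middle cingulate gyrus (R)	MCG.R	R	L
Posterior cingulate gyrus (L)	PCG.L	L	L
Posterior cingulate gyrus (R)	PCG.R	R	L
Hippocampus (L)	HIP.L	L	L
Hippocampus (R)	HIP.R	R	L
Parahippocampal gyrus (L)	PHG.L	L	L
Parahippocampal gyrus (R)	PHG.R	R	L
Amygdala (L)	AMYG.L	L	L
Amygdala (R)	AMYG.R	R	L
Calcarine fissure and surrounding cortex (L)	CAL.L	L	O
Calcarine fissure and surrounding cortex (R)	CAL.R	R	O
Cuneus (L)	CUN.L	L	O
Cuneus (R)	CUN.R	R	O
Lingual gyrus (L)	LING.L	L	O
Lingual gyrus (R)	LING.R	R	O
Superior occipital gyrus (L)	SOG.L	L	O
Superior occipital gyrus (R)	SOG.R	R	O
Middle occipital gyrus (L)	MOG.L	L	O
Middle occipital gyrus (R)	MOG.R	R	O
Inferior occipital gyrus (L)	IOG.L	L	O
Inferior occipital gyrus (R)	IOG.R	R	O
Fusiform gyrus (L)	FFG.L	L	T
Fusiform gyrus (R)	FFG.R	R	T
Postcentral gyrus (L)	PoCG.L	L	P
Postcentral gyrus (R)	PoCG.R	R	P
Superior parietal gyrus (L)	SPG.L	L	P
Superior parietal gyrus (R)	SPG.R	R	P
Inferior parietal gyrus (L)	IPL.L	L	P
Inferior parietal gyrus (R)	IPL.R	R	P
Supramarginal gyrus (L)	SMG.L	L	P
Supramarginal gyrus (R)	SMG.R	R	P
Angular gyrus (L)	ANG.L	L	P
Angular gyrus (R)	ANG.R	R	P
Precuneus (L)	PCUN.L	L	P
Precuneus (R)	PCUN.R	R	P
Paracentral lobule (L)	PCL.L	L	F
Paracentral lobule (R)	PCL.R	R	F
Heschl gyrus (L)	HES.L	L	T
Heschl gyrus (R)	HES.R	R	T
Superior temporal gyrus (L)	STG.L	L	T
Superior temporal gyrus (R)	STG.R	R	T
Temporal pole: superior temporal gyrus (L)	TPOsup.L	L	T
Temporal pole: superior temporal gyrus (R)	TPOsup.R	R	T
Middle temporal gyrus (L)	MTG.L	L	T
Middle temporal gyrus (R)	MTG.R	R	T
Temporal pole: middle temporal gyrus (L)	TPOmid.L	L	T
Temporal pole: middle temporal gyrus (R)	TPOmid.R	R	T
Inferior temporal gyrus (L)	ITG.L	L	T
Inferior temporal gyrus (R)	ITG.R	R	T
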