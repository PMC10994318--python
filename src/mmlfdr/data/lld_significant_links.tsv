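region1	region2	abbrev1	abbrev2	tF
R thalamus proper	R caudal middle frontal gyrus	RTP	RCMF	4.340
R pallidum	L inferior parietal cortex	RP	LIP	4.011
R pallidum	R caudal middle frontal gyrus	RP	RCMF	4.051
R accumbens area	L isthmus cingulate cortex	RAA	LIC	3.890
R ventral diencephalon	R fusiform gyrus	RVD	RF	4.132
L isthmus cingulate cortex	R caudal middle frontal gyrus	LIC	RCMF	4.583
L posterior cingulate cortex	R rostral middle frontal gyrus	LPC	RRMF	3.877
L posterior cingulate cortex	R supramarginal gyrus	LPC	RS	3.378
L rostral middle frontal gyrus	R caudal middle frontal gyrus	LRMF	RCMF	4.074
L superior parietal cortex	R pars opercularis	LSP	RPO	3.355
R caudal anterior cingulate cortex	R caudal middle frontal gyrus	RCAC	RCMF	3.855
R caudal middle frontal gyrus	R isthmus cingulate cortex	RCMF	RIC	3.733
R caudal middle frontal gyrus	R posterior cingulate cortex	RCMF	RPC	3.598
R pars triangularis	R rostral anterior cingulate cortex	RPT	RRAC	3.469
R posterior cingulate cortex	R supramarginal gyrus	RPC	RS	3.491
L thalamus proper	L posterior cingulate cortex	LTP	LPC	-3.701
L ventral diencephalon	R caudal anterior cingulate cortex	LVD	RCAC	-3.889
R caudate nucleus	L cuneus cortex	RCau	LCun	-3.245
L entorhinal cortex	L supramarginal gyrus	LE	LS	-3.314
L fusiform gyrus	L pars triangularis	LF	LPT	-3.864
L fusiform gyrus	L supramarginal gyrus	LF	LS	-4.332
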