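gene	r	temporal_class	annotation
F1L	0.68	Early	Large subunit of mRNA capping enzyme; transcription termination factor
F10L	0.67	Late	Ser/Thr kinase
C4L	0.66	EarlyLate	Hypothetical protein
N1L	0.66	EarlyLate	Virulence factor; inhibits apoptosis and NF-kB activation
D4R	0.64	Early	Uracil-DNA glycosylase
E4L	0.63	Early	RNA polymerase subunit
J4R	0.63	Early	DNA-dependent RNA polymerase subunit rpo22
F16L	0.61	Unknown	Recombinase superfamily
N2L	0.59	Early	Putative alpha-amanitin-sensitive protein
D1R	0.59	Early	Large subunit of mRNA capping enzyme
F14.5L	0.58	Unknown	Hypothetical protein
174	0.58	Unknown
C12L	0.58	Early	Serine protease inhibitor-like SPI-1
F11L	0.57	Unknown	Inhibition of RhoA signaling
201	0.57	Unknown
D7R	0.57	Early	DNA-dependent RNA polymerase subunit rpo18
D11L	0.57	Late	NTPase NPH-I; transcription elongation/termination/release factor
H6R	0.56	Unknown	DNA topoisomerase type I
J3R	0.56	Early	Poly(A) polymerase small subunit
K6L	0.56	Unknown	Putative monoglyceride lipase
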