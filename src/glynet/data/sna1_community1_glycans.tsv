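glycan_id	glycan_structure	rfu
2	AGP-A (AGP ConA flowthrough)	52286.06
246	Neu5Acα2-6Galβ1-4GlcNAcβ–Sp8	49625.09
263	Neu5Gcα2-6Galβ1-4GlcNAcβ–Sp0	48932.24
250	Neu5Acα2-6Galβ1-4Glcβ–Sp8	48814.18
6	Transferrin	47533.26
248	Neu5Acα2-6Galβ1-4GlcNAcb1-3Galb1-4GlcNAcb-Sp0	47165.41
42	[6OSO3]Galβ1-4Glcβ–Sp0	34505.6
44	[6OSO3]Galβ1-4GlcNAcβ–Sp8	32444.86
247	Neu5Acα2-6Galβ1-4GlcNAcb1-3Galb1-4(Fuca1-3)GlcNAcb1-3Galb1-4(Fuca1-3)GlcNAcb-Sp0	30612.85
45	[6OSO3]Galb1-4[6OSO3]Glcb-Sp8	27055.41
245	Neu5Acα2-6Galβ1-4GlcNAcβ–Sp0	26857.74
1	Alpha1-acid glycoprotein (AGP)	25869.33
43	[6OSO3]Galβ1-4Glcβ–Sp8	22740.63
86	GalNAcα1-3Galb–Sp8	21300.14
20	β-GalNAc–Sp8	20559.23
3	AGP-B (AGP ConA bound)	17780.79
72	Fucα1-2Galβ1-4GlcNAcβ–Sp8	15937.51
70	Fuca1-2Galb1-4GlcNAcb1-3Galb1-4GlcNAcb1-3Galb1-4GlcNAcb-Sp0	14916.26
69	Fucα1-2Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAc–Sp0	13165.86
87	GalNAca1-4(Fuca1-2)Galb1-4GlcNAcb-Sp8	12866.52
242	Neu5Acα2-6GalNAcα–Sp8	12071.82
90	GalNAcb1-3Gala1-4Galb1-4GlcNAcb-Sp0	11384.24
60	Fucα1-2Galβ1-3GalNAcβ1-4(Neu5Acα2-3)Galβ1-4Glcβ-Sp9	10906.21
120	Galβ1-3(Galβ1-4GlcNAcβ1-6)GalNAcα-Sp8	10546.55
150	Galβ1-4GlcNAcβ1-6(Galβ1-3)GalNAcα–Sp8	9937.06
251	Neu5Acα2-6Galβ–Sp8	9853.36
73	Fucα1-2Galβ1-4Glcβ–Sp0	9224.52
26	[3OSO3][6OSO3]Galb1-4[6OSO3]GlcNAcb-Sp0	9118.55
59	Fuca1-2Galb1-3GalNAcb1-4(Neu5Aca2-3)Galb1-4Glcb-Sp0	8069.79
74	Fucα1-2Galβ–Sp8	7769.91
122	Galb1-3(Neu5Aca2-6)GalNAca-Sp8	7693.01
10	α-GalNAc–Sp8	6840.72
40	[4OSO3]Galb1-4GlcNAcb-Sp8	6574.62
39	[4OSO3][6OSO3]Galb1-4GlcNAcb-Sp0	6514.83
241	Neu5Acα2-6(Galβ1-3)GalNAcα–Sp8	6184.61
87	GalNAca1-4(Fuca1-2)Galb1-4GlcNAcb-Sp8	5469.91
41	6-H2PO3Manα–Sp8	5447.01
249	Neu5Acα2-6Galβ1-4Glcβ–Sp0	5434.93
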