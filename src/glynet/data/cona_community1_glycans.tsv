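glycan_id	glycan_structure	rfu
144	Manα1-2Manα1-6(Manα1-3)Manα1-6(Manα2Manα2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-N	31059
139	Manα1-3(Manα1-6)Manα–Sp3	23784
136	Mana1-2Mana1-3(Mana1-2Mana1-6)Mana-Sp9	23161
138	Mana1-3(Mana1-2Mana1-2Mana1-6)Mana-Sp9	17347
137	Mana1-2Mana1-3Mana-Sp9	14700
135	Mana1-2Mana1-2Mana1-3Mana-Sp9	14334
143	Mana1-6(Mana1-2Mana1-3)Mana1-6(Manα2Manα1-3)Manb1-4GlcNAcb1-4GlcNAcb-N	12786
145	Manα1-2Manα1-2Manα1-3(Manα1-2Manα1-3(Manα1-2Manα1-6)Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-N	12581
112	α-D-Glc–Sp8	10407
75	Galβ1-4GlcNAcβ1-3Galβ1-4Glcβ–Sp8	8329
151	Neu5Gca2-3Galb1-4(Fuca1-3)GlcNAcb-Sp0	8141
59	Galβ1-3GalNAcβ1-4Galβ1-4Glcβ–Sp8	7380
113	mixed glycans: Man5-9-N–Sp1	6646
114	Manα1-6Manα1-3(Manα1-6Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-N–Sp1	6600
146	Manα1-3(Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ–Sp2	6209
6	Transferrin	5981
130	Manα1-2Manα1-6(Manα1-3)Manα1-6(Manα2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-N–Sp1	5406
129	Manα1-6(Manα1-3)Manα1-6(Manα2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-N–Sp1	5259
3	AGP-B	5076
102	Fucα1-2Galβ1-4(Fucα1-3)GlcNAcβ–Sp8	5014
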