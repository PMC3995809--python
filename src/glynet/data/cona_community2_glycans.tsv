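glycan_id	glycan_structure	rfu
193	Manα1-2Manα1-6(Manα1-3)Manα1-6(Manα2Manα2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-N	52832
194	Manα1-2Manα1-2Manα1-3(Manα1-2Manα1-3(Manα1-2Manα1-6)Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-Asn	52705
199	Man5-9mix-Asn	52238
198	Mana1-6(Mana1-3)Mana1-6(Mana1-3)Manb1-4GlcNAcb1-4 GlcNAcb-Asn	51705
196	Mana1-3(Mana1-2Mana1-2Mana1-6)Mana-Sp9	49576
192	Mana1-6(Mana1-2Mana1-3)Mana1-6(Manα2Manα1-3)Manb1-4GlcNAcb1-4GlcNAcb-Asn	48888
190	Mana1-2Mana1-3(Mana1-2Mana1-6)Mana-Sp9	44830
189	Mana1-2Mana1-2Mana1-3Mana-Sp9	43717
197	Manα1-6(Manα1-3)Manα1-6(Manα2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-N	40190
195	Manα1-3(Manα1-6)Manα–Sp9	38636
191	Mana1-2Mana1-3Mana-Sp9	35442
177	Glcα1-4Glcβ–Sp8	18139
179	Glcα1-6Glcα1-6Glcβ-Sp8	13465
178	Glcα1-4Glca–Sp8	12700
180	Glcb1-4Glcb-Sp8	6825
186	GlcAb1-6Galb-Sp8	6057
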