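glycan_id	glycan_structure	rfu
51	Manα1-6(Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp13	38866
352	Manα1-6(Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	37659
216	Manα1-6(Manα1-3)Manα1-6(Manα1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	36933
347	Manα1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAc-Sp12	35539
212	Manα1-2Manα1-6(Manα1-3)Manα1-6(Manα1-2Manα1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	35267
213	Manα1-2Manα1-6(Manα1-2Manα1-3)Manα1-6(Manα1-2Manα1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	18208
217	Manα1-6(Manα1-3)Manα1-6(Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	15856
485	Manα1-6(Manα1-3)Manβ1-4GlcNAcβ1-4(Fuca1-6)GlcNAcβ-Sp19	12002
211	Manα1-6(Manα1-2Manα1-3)Manα1-6(Manα1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	10800
417	Fuca1-2Galβ1-4(Fuca1-3)GlcNAcβ1-3GalNAca-Sp14	10154
477	Galβ1-3GlcNAcβ1-2Manα1-6(GlcNAcβ1-4)(Galβ1-3GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp21	7265
50	Manα1-6(Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	6298
349	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3Manβ1-4GlcNAcβ1-4GlcNAc-Sp12	6173
561	Gala1-3Galβ1-4GlcNAcβ1-2Manα1-6(Gala1-3Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAc-Sp24	5565
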