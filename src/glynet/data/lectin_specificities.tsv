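protein_name	specificity
Pokeweed Agglutinin	(GlcNAcb1-4)n
Datura Stramonium Lectin	(GlcNAcb1-4)n, Galb1-4GlcNAc
Soybean Agglutinin	a- or b-linked terminal GalNAc, GalNAca1-3Gal
LBA Lima Bean Agglutinin/LBL	a-D-GalN.Ac
Griffonia Simplicifolia Lectin I, Isolectin B4/GSI-B4 isolectin	a-Linked Gal
Agglutinin	a-Linked terminal GalNAc
Psophocarpus tetragonolobus Agglutinin/Basic agglutinin	a-Linked terminal GalNAc
Psophocarpus Tetragonolobus Lectin I	a-Linked terminal GalNAc
Vicia Villosa Lectin (VVL)	a-Linked terminal GalNAc, GalNAca1-3Gal
Griffonia simplicifolia II/InsecticidalN-acetylglucosamine-specific lectin	Agalactosylated tri/tetra antennary glycans, GlcNAc
Phaseolus vulgaris Erythroagglutinin/Erythroagglutinating phytohemagglutinin	Bi-antennary complex-type N-glycan with outer Galand bisecting GlcNAc
Wheat Germ Agglutinin (WGA)	Chitin oligomers, Sia
Laburnum alpinum Agglutinin/Lectin 1/Seed lectin anti-H(O)	Di-N-acetylchitobiose specific lectin.
Ulex europaeus AgglutininII/UEA-II OR Anti-H(O) lectin 2	Di-N-acetylchitobiose specific lectin.
Trichosanthes japonica Agglutinin II	Fuca1-2Galb1 -> or GalNAcb1 -> groups attheir nonreducing terminals
Cholera Toxin B	Fuca1-2Galb1-3GalNAcb1-4(Neu5Aca2-3)Galb1-4Glcb ORGalb1-3GalNAcb1-4(Neu5Aca2-3)Galb1-4Glcb
Ulex Europaeus Agglutinin ORAnti-H(O) lectin 1	Fuca1-2Galb1-4GlcNAc
Lotus Tetragonolobus Lectin/Anti-H(O) lectin	Fuca1-3(Galb1-4)GlcNAc, Fuca1-2Galb1-4GlcNAc
Aspergillus oryzae Lectin	Fuca1-6GlcNAc (core fucose)
Lens Culinaris Agglutinin	Fuca1-6GlcNAc, a-D-Glc, a-D-Man
Pisum Sativum Agglutinin	Fuca1-6GlcNAc, a-D-Glc, a-D-Man
Aleuria Aurantia Lectin AAL	Fuca1-6GlcNAc, Fuca1-3(Galb1-4)GlcNAc
Pseudomonas aeruginosa lectin/PA-I galactophilic lectin	Fucose Anywhere
Psophocarpus Tetragonolobus Lectin II	Fucose binding lectin
Fucose-binding lectin protein	Fucose binding lectin
Euonymus europaeus Agglutinin	Gala1-3Gal, blood group B antigen
Cytisus sscoparius Agglutinin	Galactose binding lectin
Discoidin-2	Galactose binding lectin
Polyporus Squamosus Lectin	Galactose binding lectin
Discoidin-1 subunit B/C	Galactose- and N-acetylgalactosamine-binding
SRL- strong binding to di-saccharideGalb1!3GalNAc-a- similar to Agaricus bisporuslectin	Galb1->3GalNAc-a-
Agaricus bisporus Agglutinin	Galb1-3GalNAc
Amaranthus Caudatus Lectin	Galb1-3GalNAc
Galactose-binding lectin (Agglutinin PNA)	Galb1-3GalNAc
Jacalin/Agglutinin alpha chain	Galb1-3GalNAc, GalNAc
Bauhinia Purpurea Lectin	Galb1-3GalNAc, GalNAc
Maclura Pomifera Lectin/Agglutinin alpha chain/MPA	Galb1-3GalNAc, GalNAc
Erythrina crista-galli Lectin	Galb1-4GlcNAc
Ricinus Communis Agglutinin I	Galb1-4GlcNAc
Dolichos biflorus Agglutinin/Seed lectin subunit I	GalNAca1-3GalNAc, blood group A antigen
Wisteria floribunda Agglutinin	GalNAcb1-4GlcNAc, Galb1-3(-6)GalNAc
Marasmium oreades agglutinin	Galα(1,3)Gal
Solanum Tuberosum (Potato) Lectin (STL)	GlcNAc oligomers, oligosaccharide containingGlcNAc and LacNAc
Lycopersicon Esculentum Lectin	GlcNAc trimers/tetramers
Urtica dioica Agglutinin/Lectin/endochitinase 1	GlcNAcb1-4GlcNAc, Mixture of Man5–Man9
Coprinopsis cinerea lectin 2	GlcNAcβ1,4[Fucα1,3]GlcNAc
Vicia faba Agglutinin	Glucose binding lectin
Galanthus nivalis agglutinin orMannose-specific lectin	High-mannose, Mana1-3Man
Hippeastrum hybrid Agglutinin	High-mannose, Mana1-3Man, Mana1-6Man
Canavalia A (Con A)	High-mannose, Mana1-6(Mana1-3)Man
Canavalia ensiformis (Con A)	High-mannose, Mana1-6(Mana1-3)Man
Narcissus pseudonarcissusAgglutinin	High-mannose, Mana1-6Man
Tulip Lectin	Mana1-3(Mana1-6)Man, bi- and tri-antennarycomplex-type N-glycan, GalNAc
Sauromatum gutattum	Manb Anywhere
Mannose specific lectin	Mannose binding lectin
ASA, Allium sativum agglutinin(ASAI and ASAII)	Mannose binding lectin
Lectin	Mannose binding lectin
Concanavalin-A	Mannose binding lectin
Colocasia esculenta Lectin	Mannose binding lectin
Lectin alpha chain	Mannose binding lectin
Mannose-binding lectin	Mannose binding lectin
Banana lectin	Mannose binding lectin
Cyanovirin-N	Mannose binding lectin
Salt stress-induced protein	Mannose binding lectin
Lectin-like protein	Mannose binding lectin
Hessian fly response gene 1 protein	Mannose binding lectin
Nessun dorma, isoform A;Nessun dorma, isoform B	N-acetylglucosamine
Nicotiana tabacum agglutinin	N-acetylglucosamine
Psathyrella velutina lectin	N-acetylglucosamine and N-acetylneuraminic acid
Ricin B-like lectin	N,N'-diacetyllactosediamine(GalNAcβ1-4GlcNAc, LacdiNAc)
Maackia Amurensis Lectin II	Siaa2-3Galb1-
Maackia Amurensis Lectin I	Siaa2-3Galb1-
Maackia amurensis Agglutinin	Siaa2-3Galb1-3(Siaa2-6)GalNAc
Sambucus nigra Agglutinin	Siaa2-6Gal/GalNAc
Trichosanthes japonica Agglutinin I	Siaa2-6Gal/GalNAc
Limax flavus Agglutinin/Sialic acid-binding lectin 1	Sialic acid-binding lectin
Platypodium elegans legume lectin	Subterminal Mannose
Sclerotinia sclerotiorumagglutinin	terminal N-acetylgalactosamine (GalNAc)
Phaseolus vulgaris Leucoagglutinin/Leucoagglutinating phytohemagglutinin	Tri/tetra-antennary complex-type N-glycan
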