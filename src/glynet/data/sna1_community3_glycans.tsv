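glycan_id	glycan_structure	rfu
268	Neu5Acα2-6Galβ1-4(6S)GlcNAcβ-Sp8	51134
467	Neu5Acα2-6Galβ1-4GlcNAcβ1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-2)Manα1-6(GlcNAcβ1-4)(Neu5Acα2-6Galβ1-4GlcNAcβ1-4(Neu5Acα2-6Galβ1-4GlcNAcβ1-2)Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp21	48246
465	Neu5Acα2-6Galβ1-4GlcNAcβ1-4Manα1-6(GlcNAcβ1-4)(Neu5Acα2-6Galβ1-4GlcNAcβ1-4(Neu5Acα2-6Galβ1-4GlcNAcβ1-2)Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp21	43978
346	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6(Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAc-Sp12	43812
327	Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ-Sp0	41668
320	Galβ1-4GlcNAcβ1-2Manα1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	41588
302	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6(Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	41500
483	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4(Fucα1-6)GlcNAcβ-Sp24	41106
55	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	40488
348	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6Manβ1-4GlcNAcβ1-4GlcNAc-Sp12	39574
606	Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ1-3)GalNAca-Sp14	39290
482	Neu5Acα2-6Galβ1-4 GlcNAcβ1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-3)GalNAca-Sp14	39202
57	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Man-a1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp21	38592
56	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp13	37417
609	Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ1-2Manα1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	36652
457	Neu5Acα2-6Galβ1-4GlcNAcβ1-6(Fucα1-2Galβ1-3GlcNAcβ1-3)Galβ1-4Glc-Sp21	36616
325	Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-3GlcNAcβ-Sp0	36221
314	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3(Galβ1-4GlcNAcβ1-2Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	35848
503	Neu5Acα2-6GalNAcβ1-4(6S)GlcNAcβ-Sp8	33405
298	(6S)Galβ1-4(6S)GlcNAcβ-Sp0	32632
287	Neu5Gcα2-6Galβ1-4GlcNAcβ-Sp0	31718
354	Galβ1-4GlcNAcβ1-2Manα1-6(Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4(Fucα1-6)GlcNAcβ-Sp22	30544
557	Neu5Gcα2-8Neu5Gcα2-6Galβ1-4GlcNAc-Sp0	28273
366	Fucα1-4(Galβ1-3)GlcNAcβ1-2Manα1-6(Fucα1-4(Galβ1-3)GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4(Fucα1-6)GlcNAcβ-Sp22	27993
319	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6(Neu5Aca2-3Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	27611
54	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-N(LT)AVL	27447
321	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3(Neu5Aca2-3Galβ1-4GlcNAcβ1-2Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	26481
274	Neu5Acα2-6Galβ1-4Glcb-Sp8	25380
53	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	25345
48	[9NAc]Neu5Acα2-6Galβ1-4GlcNAcβ-Sp8	21953
488	Neu5Acα2-6Galβ1-4GlcNAcβ1-6(Fucα1-2Galβ1-4(Fucα1-3)GlcNAcβ1-3)Galβ1-4Glc-Sp21	21783
328	Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-3GlcNAcβ-Sp0	21014
324	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3(Neu5Acα2-3Galβ1-4GlcNAcβ1-2Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	19830
58	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp24	18639
347	Manα1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAc-Sp12	16329
464	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6(GlcNAcβ1-4)(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp21	16237
466	Neu5Acα2-6Galβ1-4GlcNAcβ1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-2)Manα1-6(GlcNAcβ1-4)(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp21	13858
409	Neu5Acα2-6Galβ1-3GlcNAcβ1-3(Galβ1-4GlcNAcβ1-6)Galβ1-4Glc-Sp21	12386
270	Neu5Acα2-6Galβ1-4GlcNAcβ-Sp8	11415
317	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3(Galβ1-4GlcNAcβ1-2Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	11124
360	KDNa2-3Galβ1-3GalNAca-Sp14	11019
485	Manα1-6(Manα1-3)Manβ1-4GlcNAcβ1-4(Fucα1-6)GlcNAcβ-Sp19	10968
427	Fucα1-2Galβ1-3GlcNAcβ1-2Manα1-6(Fucα1-2Galβ1-3GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4(Fucα1-6)GlcNAcβ-Sp22	10833
458	Neu5Acα2-6Galβ1-4GlcNAcβ1-6(Fucα1-2Galβ1-3GlcNAcβ1-3)Galβ-4Glc-Sp21	10202
52	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp8	9467
309	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6(GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	9381
376	Neu5Acα2-6Galβ1-4GlcNAcβ1-3GalNAc-Sp14	8974
521	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Man-Sp0	8470
313	Neu5Acα2-3Galβ1-4GlcNAcβ1-2Manα1-3(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	8322
316	Neu5Acα2-3Galβ1-4GlcNAcβ1-2Manα1-3(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	8189
353	GlcNAcβ1-2Manα1-6(GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4(Fucα1-6)GlcNAcβ-Sp22	7768
527	Neu5Acα2-3Galβ1-3GlcNAcβ1-2Manα-Sp0	6941
478	Neu5Acα2-6Galβ1-4GlcNAcβ1-6(Galβ1-3GlcNAcβ1-3)Galβ1-4Glcb-Sp21	6901
315	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3(GlcNAcβ1-2Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	6606
358	KDNa2-6Galβ1-4GlcNAc-Sp0	6532
333	Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ-Sp0	6339
349	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3Manβ1-4GlcNAcβ1-4GlcNAc-Sp12	6178
607	Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ1-2Manα1-6(Neu5Acα2-6Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ1-3Galβ1-4GlcNAcβ1-2Manα1-3)Manβ1-4GlcNAcβ1-4GlcNAcβ-Sp12	6161
479	Neu5Aca2-3Galβ1-4GlcNAcβ1-2Manα-Sp0	6154
51	Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-3(Neu5Acα2-6Galβ1-4GlcNAcβ1-2Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAcβ-N(LT)AVL	5582
49	Neu5,9Ac2a2-6Galβ1-4GlcNAcβ-Sp8	5207
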