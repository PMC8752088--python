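# Synthetic haemoglobin extinction spectra (NOT measured data).
# Parametric Gaussian-band approximation of the qualitative visible-range
# oxy-/deoxy-haemoglobin spectra (alpha/beta bands at 542/577 nm, broad
# deoxy band at 556 nm, Soret-edge tails), generated by
# oispec.spectra.synthetic_extinction; see scripts/make_extinction_table.py.
# Coefficients are Napierian (natural-log) molar extinction, 1/(M*cm).
# Sampled every 1 nm over 450-650 nm.
wavelength_nm	eps_hbo	eps_hbr
450	161345	208333
451	161232	204215
452	160859	199989
453	160227	195665
454	159340	191255
455	158203	186770
456	156822	182222
457	155203	177621
458	153355	172979
459	151286	168307
460	149008	163616
461	146531	158917
462	143867	154221
463	141029	149537
464	138030	144877
465	134884	140249
466	131605	135664
467	128208	131130
468	124709	126656
469	121121	122251
470	117460	117923
471	113742	113679
472	109981	109527
473	106192	105474
474	102390	101525
475	98587.8	97687
476	94800.1	93965.6
477	91039.7	90365.6
478	87319.2	86891.9
479	83650.5	83548.6
480	80044.7	80339.7
481	76512.6	77268.5
482	73063.8	74338.2
483	69707.3	71551.3
484	66451.5	68910.1
485	63303.8	66416.6
486	60270.9	64072.2
487	57358.7	61878
488	54572.2	59835.1
489	51915.8	57943.8
490	49393.2	56204.3
491	47007.2	54616.5
492	44760	53180
493	42653.1	51894.2
494	40687.4	50757.9
495	38863.2	49770.1
496	37180.2	48929.2
497	35637.7	48233.6
498	34234.3	47681.1
499	32968.3	47269.8
500	31837.7	46997.2
501	30840	46860.6
502	29972.2	46857.4
503	29231.4	46984.5
504	28614.1	47238.7
505	28116.7	47616.6
506	27735.5	48114.8
507	27466.6	48729.5
508	27305.8	49456.8
509	27249.3	50292.7
510	27292.8	51233
511	27432.4	52273.3
512	27664.5	53409.1
513	27985.8	54635.7
514	28393.8	55948.4
515	28887.2	57342.3
516	29466.4	58812.1
517	30134.1	60352.7
518	30896.6	61958.9
519	31764.8	63625.1
520	32755.2	65345.8
521	33891.6	67115.4
522	35206.3	68928.1
523	36740.7	70778.1
524	38545.9	72659.4
525	40681.4	74566.1
526	43213.3	76492.2
527	46209.9	78431.5
528	49736.2	80378.1
529	53845.8	82325.7
530	58572.5	84268.3
531	63920.1	86199.7
532	69853.8	88113.9
533	76292.6	90004.9
534	83105.6	91866.6
535	90112.5	93693.2
536	97089.7	95478.9
537	103782	97217.9
538	109920	98904.8
539	115238	100534
540	119502	102101
541	122522	103599
542	124178	105025
543	124426	106373
544	123304	107640
545	120927	108821
546	117476	109911
547	113183	110909
548	108306	111809
549	103109	112609
550	97843.3	113307
551	92727.3	113900
552	87938.5	114386
553	83606.6	114763
554	79813.6	115030
555	76599.5	115185
556	73970.5	115229
557	71910.3	115160
558	70391.4	114980
559	69386	114687
560	68875.2	114283
561	68854.8	113770
562	69338.4	113147
563	70355.7	112418
564	71946.5	111583
565	74151.3	110646
566	76997.6	109609
567	80485.6	108475
568	84572.5	107247
569	89160.1	105929
570	94088.3	104524
571	99134.9	103036
572	104025	101469
573	108452	99827.5
574	112099	98115.7
575	114677	96338.2
576	115950	94499.7
577	115765	92604.8
578	114073	90658.5
579	110928	88665.5
580	106488	86630.7
581	100992	84559.2
582	94735.1	82455.8
583	88036	80325.4
584	81205.1	78172.8
585	74518.5	76002.8
586	68197.6	73820.1
587	62399.9	71629.4
588	57216.5	69435.1
589	52679	67241.6
590	48769.8	65053.1
591	45436.6	62873.7
592	42605.4	60707.4
593	40193.4	58557.8
594	38118.4	56428.6
595	36305.4	54323.2
596	34690.2	52244.7
597	33221.2	50196.1
598	31858.4	48180.2
599	30572.9	46199.7
600	29344.1	44256.8
601	28158.5	42353.8
602	27007.5	40492.6
603	25885.9	38675
604	24791.1	36902.5
605	23721.8	35176.5
606	22677.7	33498.1
607	21658.8	31868.3
608	20665.8	30287.9
609	19699	28757.4
610	18759	27277.3
611	17846.3	25847.9
612	16961.2	24469.2
613	16104.1	23141.1
614	15275.3	21863.6
615	14474.8	20636.1
616	13702.7	19458.4
617	12959	18329.7
618	12243.6	17249.5
619	11556.2	16216.9
620	10896.7	15231.1
621	10264.7	14291.1
622	9659.73	13395.8
623	9081.48	12544.3
624	8529.42	11735.3
625	8003.01	10967.6
626	7501.67	10240
627	7024.8	9551.26
628	6571.75	8900.04
629	6141.85	8285.03
630	5734.4	7704.91
631	5348.7	7158.34
632	4984.02	6643.97
633	4639.62	6160.48
634	4314.75	5706.53
635	4008.67	5280.81
636	3720.62	4882.03
637	3449.87	4508.91
638	3195.66	4160.19
639	2957.26	3834.66
640	2733.94	3531.11
641	2524.99	3248.37
642	2329.71	2985.33
643	2147.41	2740.88
644	1977.42	2513.96
645	1819.09	2303.55
646	1671.78	2108.67
647	1534.89	1928.37
648	1407.82	1761.74
649	1289.99	1607.92
650	1180.85	1466.09
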