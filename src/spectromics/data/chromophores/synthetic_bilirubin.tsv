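# bilirubin, 1/mm per mol/L (synthetic reconstruction)
# wavelength_nm	mu_a
400	6448.4
402	6697
404	6948.36
406	7201.88
408	7456.91
410	7712.77
412	7968.7
414	8223.93
416	8477.63
418	8728.91
420	8976.86
422	9220.55
424	9458.98
426	9691.16
428	9916.07
430	10132.7
432	10339.9
434	10536.7
436	10722.1
438	10895
440	11054.4
442	11209.6
444	11367.7
446	11524.7
448	11676.2
450	11817.7
452	11944.5
454	12051.6
456	12134.2
458	12187.2
460	12205.9
462	12153.8
464	12006.7
466	11779.4
468	11487.9
470	11147.9
472	10774.8
474	10382.7
476	9984.29
478	9590.87
480	9212
482	8812.66
484	8363.7
486	7881.73
488	7381.92
490	6877.6
492	6379.93
494	5897.95
496	5438.57
498	5006.81
500	4606
502	4219.35
504	3836.45
506	3467.08
508	3118.43
510	2795.34
512	2500.61
514	2235.43
516	1999.7
518	1792.44
520	1612.1
522	1452.77
524	1308.84
526	1179
528	1061.98
530	956.629
532	861.869
534	776.702
536	700.21
538	631.552
540	569.957
542	514.722
544	465.208
546	420.833
548	381.072
550	345.45
552	313.402
554	284.437
556	258.251
558	234.569
560	213.146
562	193.76
564	176.211
566	160.32
568	145.926
570	132.882
572	121.059
574	110.337
576	100.611
578	91.7857
580	83.774
582	76.4982
584	69.8884
586	63.8812
588	58.4195
590	53.4518
592	48.9317
594	44.8171
596	41.07
598	37.6563
600	34.545
602	31.6946
604	29.0723
606	26.6631
608	24.452
610	22.4251
612	20.5688
614	18.8702
616	17.3172
618	15.8983
620	14.6029
622	13.4208
624	12.3427
626	11.36
628	10.4644
630	9.64855
632	8.90557
634	8.22911
636	7.61333
638	7.05288
640	6.54288
642	6.07885
644	5.6567
646	5.27272
648	4.92351
650	4.606
652	4.3147
654	4.04484
656	3.79471
658	3.56278
660	3.34762
662	3.14793
664	2.9625
666	2.79025
668	2.63015
670	2.4813
672	2.34283
674	2.21396
676	2.09397
678	1.98221
680	1.87806
682	1.78096
684	1.69041
686	1.60591
688	1.52704
690	1.4534
692	1.38461
694	1.32033
696	1.26024
698	1.20405
700	1.1515
702	1.10222
704	1.05585
706	1.01219
708	0.971039
710	0.932209
712	0.895536
714	0.860867
716	0.828061
718	0.796988
720	0.767529
722	0.739572
724	0.713017
726	0.687769
728	0.66374
730	0.640851
732	0.619027
734	0.598198
736	0.5783
738	0.559275
740	0.541066
742	0.523623
744	0.506898
746	0.490846
748	0.475426
750	0.4606
752	0.446344
754	0.432643
756	0.419477
758	0.406823
760	0.394662
762	0.382974
764	0.371742
766	0.360948
768	0.350574
770	0.340604
772	0.331023
774	0.321816
776	0.312967
778	0.304464
780	0.296293
782	0.288442
784	0.280897
786	0.273648
788	0.266684
790	0.259993
792	0.253566
794	0.247392
796	0.241462
798	0.235768
800	0.2303
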