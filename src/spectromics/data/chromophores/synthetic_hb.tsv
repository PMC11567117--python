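# deoxyhemoglobin, whole blood 150 g/L, 1/mm (synthetic reconstruction)
# wavelength_nm	mu_a
400	119.435
402	140.418
404	161.569
406	182.223
408	201.757
410	219.635
412	235.446
414	248.923
416	259.951
418	268.559
420	274.901
422	279.236
424	281.899
426	283.276
428	283.785
430	283.858
432	270.491
434	236.851
436	194.009
438	151.338
440	114.447
442	85.417
444	64.0506
446	49.1238
448	39.2289
450	33.206
452	29.1173
454	25.5818
456	22.5716
458	20.0468
460	17.9633
462	16.2774
464	14.9502
466	13.95
468	13.2547
470	12.854
472	12.6205
474	12.423
476	12.2555
478	12.1128
480	11.9899
482	11.882
484	11.7848
486	11.694
488	11.6054
490	11.515
492	11.4165
494	11.3159
496	11.2272
498	11.1641
500	11.1401
502	11.2731
504	11.6216
506	12.1116
508	12.6615
510	13.1753
512	13.6416
514	14.1268
516	14.6407
518	15.1941
520	15.7997
522	16.5011
524	17.3237
526	18.2515
528	19.2641
530	20.3356
532	21.4333
534	22.5168
536	23.5383
538	24.4432
540	25.1723
542	25.8048
544	26.4429
546	27.0577
548	27.6178
550	28.0895
552	28.438
554	28.6283
556	28.6479
558	28.6088
560	28.5465
562	28.4261
564	28.2051
566	27.8901
568	27.4881
570	27.007
572	26.455
574	25.8406
576	25.1723
578	24.1049
580	22.497
582	20.6471
584	18.8011
586	17.1386
588	15.5554
590	13.9458
592	12.4133
594	11.0264
596	9.82439
598	8.82522
600	8.03372
602	7.38868
604	6.82067
606	6.31849
608	5.87278
610	5.47563
612	5.12038
614	4.80136
616	4.51375
618	4.25343
620	4.01686
622	3.79937
624	3.59763
626	3.41057
628	3.23718
630	3.07653
632	2.92775
634	2.79004
636	2.66265
638	2.54489
640	2.43613
642	2.33578
644	2.24331
646	2.15823
648	2.08007
650	2.00843
652	1.94319
654	1.88384
656	1.82947
658	1.77928
660	1.73256
662	1.68867
664	1.647
666	1.60703
668	1.56827
670	1.53027
672	1.49263
674	1.45499
676	1.41701
678	1.37842
680	1.33895
682	1.29809
684	1.25608
686	1.21378
688	1.17199
690	1.13138
692	1.09255
694	1.05599
696	1.02215
698	0.991392
700	0.964047
702	0.939248
704	0.91585
706	0.893737
708	0.8728
710	0.852941
712	0.834067
714	0.816093
716	0.79894
718	0.782534
720	0.766807
722	0.751695
724	0.737138
726	0.72308
728	0.709469
730	0.696256
732	0.683487
734	0.671226
736	0.659452
738	0.648145
740	0.637287
742	0.62686
744	0.616848
746	0.607233
748	0.598002
750	0.58914
752	0.580548
754	0.57214
756	0.563915
758	0.555874
760	0.548016
762	0.540342
764	0.53285
766	0.52554
768	0.518412
770	0.511466
772	0.5047
774	0.498113
776	0.491706
778	0.485477
780	0.479426
782	0.473551
784	0.467851
786	0.462326
788	0.456975
790	0.451797
792	0.44679
794	0.441954
796	0.437289
798	0.432793
800	0.428465
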