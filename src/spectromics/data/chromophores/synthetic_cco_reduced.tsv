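# reduced cytochrome-c oxidase, 1/mm per mol/L (synthetic reconstruction)
# wavelength_nm	mu_a
400	11515
402	12429.7
404	13363.4
406	14296.4
408	15204.4
410	16059.5
412	16830.7
414	17485.1
416	17989.2
418	18311.4
420	18424
422	18376
424	18237.8
426	18018.4
428	17728
430	17377
432	16975.9
434	16535.3
436	16065.1
438	15574.7
440	15072.9
442	14567.5
444	14065.6
446	13546.1
448	12867
450	12050.7
452	11147.8
454	10204.2
456	9258.59
458	8341.78
460	7476.34
462	6677.34
464	5953.49
466	5308.38
468	4741.8
470	4250.92
472	3831.35
474	3477.89
476	3185.27
478	2948.55
480	2763.6
482	2606.88
484	2457.65
486	2316.55
488	2184
490	2060.25
492	1945.4
494	1839.46
496	1742.32
498	1653.83
500	1573.78
502	1501.96
504	1438.13
506	1382.07
508	1333.59
510	1292.53
512	1258.79
514	1232.34
516	1213.21
518	1201.53
520	1197.56
522	1206.79
524	1233.15
526	1275.02
528	1331.08
530	1400.07
532	1480.55
534	1570.69
536	1668.11
538	1769.67
540	1871.39
542	1968.38
544	2054.94
546	2124.71
548	2171.12
550	2187.85
552	2182.36
554	2166.99
556	2143.44
558	2113.48
560	2078.82
562	2041.16
564	2002.06
566	1963.03
568	1925.44
570	1890.55
572	1859.55
574	1833.56
576	1813.63
578	1800.86
580	1796.34
582	1828.97
584	1922.64
586	2074.06
588	2282.1
590	2545.61
592	2861.24
594	3220.89
596	3609.25
598	4001.59
600	4362.95
602	4649.63
604	4813.97
606	4814.95
608	4655.92
610	4373.69
612	4010.73
614	3607.71
616	3198.73
618	2809.07
620	2455.22
622	2146.16
624	1885.3
626	1672.43
628	1505.46
630	1381.8
632	1283.65
634	1194.23
636	1112.87
638	1038.92
640	971.796
642	910.952
644	855.881
646	806.121
648	761.25
650	720.886
652	684.682
654	652.327
656	623.544
658	598.09
660	575.75
662	555.18
664	535.24
666	516.028
668	497.63
670	480.114
672	463.537
674	447.943
676	433.367
678	419.839
680	407.378
682	396.004
684	385.731
686	376.573
688	368.546
690	361.666
692	355.954
694	351.437
696	348.15
698	346.136
700	345.45
702	345.501
704	345.652
706	345.898
708	346.237
710	346.664
712	347.176
714	347.77
716	348.442
718	349.189
720	350.007
722	350.893
724	351.844
726	352.855
728	353.924
730	355.048
732	356.222
734	357.443
736	358.708
738	360.013
740	361.354
742	362.729
744	364.132
746	365.561
748	367.012
750	368.48
752	370.056
754	371.832
756	373.802
758	375.965
760	378.316
762	380.854
764	383.574
766	386.475
768	389.553
770	392.806
772	396.231
774	399.825
776	403.586
778	407.51
780	411.596
782	415.84
784	420.239
786	424.79
788	429.489
790	434.334
792	439.32
794	444.444
796	449.702
798	455.088
800	460.6
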