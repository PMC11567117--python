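# oxidized cytochrome-c oxidase, 1/mm per mol/L (synthetic reconstruction)
# wavelength_nm	mu_a
400	10363.5
402	11235.4
404	12089.5
406	12908.3
408	13673
410	14364.7
412	14964.4
414	15454.4
416	15818.8
418	16044.3
420	16121
422	16013.8
424	15709.6
426	15238.6
428	14634.3
430	13931.2
432	13162.3
434	12358
436	11544.4
438	10743.5
440	9972.65
442	9245.01
444	8569.9
446	7953.46
448	7399.28
450	6909
452	6435.29
454	5944.17
456	5453.69
458	4978.18
460	4528.32
462	4111.45
464	3732.08
466	3392.42
468	3092.97
470	2833.05
472	2611.28
474	2425.91
476	2275.23
478	2157.8
480	2072.7
482	2005.4
484	1941.63
486	1881.38
488	1824.66
490	1771.44
492	1721.71
494	1675.44
496	1632.6
498	1593.16
500	1557.1
502	1524.39
504	1495.02
506	1468.98
508	1446.27
510	1426.9
512	1410.91
514	1398.33
516	1389.22
518	1383.68
520	1381.8
522	1383.21
524	1387.18
526	1393.35
528	1401.34
530	1410.77
532	1421.29
534	1432.49
536	1443.98
538	1455.36
540	1466.21
542	1476.08
544	1484.54
546	1491.14
548	1495.42
550	1496.95
552	1495.27
554	1490.36
556	1482.46
558	1471.81
560	1458.67
562	1443.31
564	1425.98
566	1406.94
568	1386.47
570	1364.81
572	1342.21
574	1318.9
576	1295.11
578	1271.06
580	1246.93
582	1222.91
584	1199.18
586	1175.9
588	1153.2
590	1131.24
592	1110.13
594	1089.98
596	1070.9
598	1053
600	1036.35
602	1020.18
604	1003.71
606	987.023
608	970.208
610	953.343
612	936.504
614	919.761
616	903.18
618	886.821
620	870.743
622	854.997
624	839.632
626	824.693
628	810.22
630	796.252
632	782.823
634	769.965
636	757.709
638	746.082
640	735.109
642	724.816
644	715.225
646	706.361
648	698.245
650	690.9
652	683.94
654	676.985
656	670.065
658	663.208
660	656.444
662	649.798
664	643.297
666	636.965
668	630.826
670	624.903
672	619.217
674	613.79
676	608.643
678	603.794
680	599.265
682	595.073
684	591.238
686	587.78
688	584.716
690	582.067
692	579.852
694	578.092
696	576.806
698	576.018
700	575.75
702	575.922
704	576.427
706	577.249
708	578.372
710	579.781
712	581.461
714	583.397
716	585.575
718	587.98
720	590.598
722	593.413
724	596.411
726	599.578
728	602.898
730	606.355
732	609.934
734	613.618
736	617.392
738	621.238
740	625.14
742	629.079
744	633.037
746	636.997
748	640.937
750	644.84
752	648.822
754	653.014
756	657.415
758	662.024
760	666.841
762	671.865
764	677.095
766	682.532
768	688.173
770	694.02
772	700.072
774	706.328
776	712.789
778	719.453
780	726.32
782	733.39
784	740.662
786	748.136
788	755.811
790	763.687
792	771.763
794	780.038
796	788.512
798	797.183
800	806.05
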