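# oxyhemoglobin, whole blood 150 g/L, 1/mm (synthetic reconstruction)
# wavelength_nm	mu_a
400	142.465
402	169.279
404	195.937
406	221.041
408	243.165
410	260.995
412	273.46
414	279.843
416	278.963
418	266.781
420	246.138
422	221.1
424	195.144
426	170.786
428	149.572
430	132.289
432	116.935
434	101.902
436	87.916
438	75.4133
440	64.5895
442	55.469
444	47.9683
446	41.9483
448	37.2538
450	33.7416
452	30.9909
454	28.6156
456	26.5549
458	24.7592
460	23.1874
462	21.8057
464	20.5855
466	19.5031
468	18.5383
470	17.6742
472	16.8874
474	16.1629
476	15.4981
478	14.8903
480	14.3372
482	13.8363
484	13.3857
486	12.9836
488	12.6282
490	12.3184
492	12.0424
494	11.7928
496	11.5742
498	11.3909
500	11.2472
502	11.1241
504	11.0079
506	10.9105
508	10.8436
510	10.8187
512	10.9422
514	11.28
516	11.7878
518	12.4197
520	13.1217
522	14.1088
524	15.5645
526	17.3469
528	19.2327
530	20.8877
532	22.3927
534	24.0294
536	25.6543
538	27.0846
540	28.1057
542	28.4929
544	28.0207
546	26.8734
548	25.4506
550	24.1012
552	22.5674
554	20.7498
556	19.0908
558	17.9103
560	17.46
562	17.9961
564	19.3855
566	21.2944
568	23.2745
570	24.8878
572	26.6819
574	28.4129
576	29.5555
578	29.3963
580	27.1344
582	23.6465
584	19.9182
586	16.603
588	13.112
590	9.47045
592	6.48464
594	4.36325
596	2.99045
598	2.16401
600	1.71386
602	1.44956
604	1.24591
606	1.08632
608	0.959132
610	0.856018
612	0.770904
614	0.699299
616	0.637823
618	0.583908
620	0.535581
622	0.491459
624	0.451174
626	0.414604
628	0.381584
630	0.351928
632	0.325431
634	0.301887
636	0.28109
638	0.262846
640	0.246972
642	0.233303
644	0.221696
646	0.21203
648	0.204209
650	0.198165
652	0.193112
654	0.188306
656	0.183767
658	0.179512
660	0.175557
662	0.171913
664	0.168596
666	0.165616
668	0.162986
670	0.160718
672	0.158825
674	0.157322
676	0.156223
678	0.155549
680	0.155319
682	0.155319
684	0.155319
686	0.155319
688	0.155319
690	0.155319
692	0.155319
694	0.155319
696	0.155319
698	0.155319
700	0.155319
702	0.155676
704	0.15671
706	0.158366
708	0.160596
710	0.163357
712	0.166603
714	0.17029
716	0.174371
718	0.178794
720	0.183503
722	0.188437
724	0.193523
726	0.198685
728	0.203835
730	0.208877
732	0.214205
734	0.220224
736	0.226835
738	0.233932
740	0.241391
742	0.249071
744	0.256813
746	0.264435
748	0.271737
750	0.278502
752	0.284971
754	0.291532
756	0.298178
758	0.3049
760	0.311689
762	0.318533
764	0.325421
766	0.332341
768	0.33928
770	0.346225
772	0.353159
774	0.360069
776	0.366937
778	0.373746
780	0.380478
782	0.387115
784	0.393638
786	0.400025
788	0.406257
790	0.412313
792	0.418171
794	0.423808
796	0.429203
798	0.434334
800	0.439177
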