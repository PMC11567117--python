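# epidermal melanin, 1/mm at unit volume fraction (power-law approximation)
# wavelength_nm	mu_a
400	140.228
402	137.919
404	135.658
406	133.446
408	131.28
410	129.159
412	127.083
414	125.05
416	123.06
418	121.11
420	119.2
422	117.329
424	115.496
426	113.7
428	111.941
430	110.216
432	108.526
434	106.87
436	105.246
438	103.654
440	102.094
442	100.563
444	99.0628
446	97.5912
448	96.148
450	94.7323
452	93.3437
454	91.9814
456	90.6448
458	89.3334
460	88.0466
462	86.7837
464	85.5443
466	84.3278
468	83.1337
470	81.9615
472	80.8107
474	79.6809
476	78.5715
478	77.482
480	76.4122
482	75.3615
484	74.3294
486	73.3157
488	72.3199
490	71.3416
492	70.3805
494	69.4361
496	68.5081
498	67.5962
500	66.7
502	65.8192
504	64.9535
506	64.1025
508	63.2659
510	62.4435
512	61.6349
514	60.8399
516	60.0582
518	59.2895
520	58.5335
522	57.7901
524	57.0588
526	56.3396
528	55.632
530	54.936
532	54.2513
534	53.5776
536	52.9148
538	52.2626
540	51.6208
542	50.9892
544	50.3676
546	49.7559
548	49.1538
550	48.5611
552	47.9776
554	47.4033
556	46.8378
558	46.2811
560	45.733
562	45.1933
564	44.6618
566	44.1385
568	43.623
570	43.1154
572	42.6155
574	42.123
576	41.6379
578	41.1601
580	40.6893
582	40.2256
584	39.7687
586	39.3185
588	38.8749
590	38.4378
592	38.0071
594	37.5826
596	37.1643
598	36.752
600	36.3456
602	35.9451
604	35.5503
606	35.1611
608	34.7774
610	34.3991
612	34.0262
614	33.6585
616	33.296
618	32.9385
620	32.586
622	32.2384
624	31.8956
626	31.5576
628	31.2241
630	30.8953
632	30.5709
634	30.2509
636	29.9353
638	29.624
640	29.3168
642	29.0138
644	28.7148
646	28.4198
648	28.1288
650	27.8416
652	27.5582
654	27.2786
656	27.0026
658	26.7303
660	26.4615
662	26.1962
664	25.9344
666	25.676
668	25.4209
670	25.1691
672	24.9205
674	24.6751
676	24.4328
678	24.1936
680	23.9575
682	23.7243
684	23.4941
686	23.2668
688	23.0423
690	22.8207
692	22.6018
694	22.3856
696	22.1721
698	21.9613
700	21.753
702	21.5473
704	21.3442
706	21.1435
708	20.9452
710	20.7494
712	20.556
714	20.3648
716	20.176
718	19.9895
720	19.8052
722	19.6231
724	19.4431
726	19.2654
728	19.0897
730	18.9161
732	18.7445
734	18.575
736	18.4074
738	18.2418
740	18.0782
742	17.9164
744	17.7565
746	17.5985
748	17.4423
750	17.2879
752	17.1353
754	16.9844
756	16.8352
758	16.6877
760	16.5419
762	16.3978
764	16.2553
766	16.1144
768	15.9751
770	15.8373
772	15.7011
774	15.5664
776	15.4332
778	15.3015
780	15.1712
782	15.0424
784	14.915
786	14.789
788	14.6644
790	14.5411
792	14.4192
794	14.2986
796	14.1793
798	14.0613
800	13.9446
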