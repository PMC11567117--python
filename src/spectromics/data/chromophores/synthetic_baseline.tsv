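# bloodless skin baseline absorption, 1/mm (exponential approximation)
# wavelength_nm	mu_a
400	0.0231942
402	0.0225765
404	0.0219773
406	0.0213959
408	0.0208317
410	0.0202844
412	0.0197534
414	0.0192381
416	0.0187382
418	0.0182532
420	0.0177826
422	0.017326
424	0.016883
426	0.0164532
428	0.0160362
430	0.0156315
432	0.015239
434	0.0148581
436	0.0144885
438	0.0141299
440	0.0137821
442	0.0134445
444	0.013117
446	0.0127993
448	0.012491
450	0.0121919
452	0.0119017
454	0.0116201
456	0.0113469
458	0.0110818
460	0.0108247
462	0.0105751
464	0.010333
466	0.0100981
468	0.00987023
470	0.00964911
472	0.00943457
474	0.00922641
476	0.00902445
478	0.0088285
480	0.00863838
482	0.00845392
484	0.00827495
486	0.0081013
488	0.00793282
490	0.00776936
492	0.00761076
494	0.00745688
496	0.00730758
498	0.00716272
500	0.00702217
502	0.00688581
504	0.0067535
506	0.00662514
508	0.00650059
510	0.00637975
512	0.0062625
514	0.00614874
516	0.00603837
518	0.00593129
520	0.00582739
522	0.00572658
524	0.00562877
526	0.00553387
528	0.0054418
530	0.00535247
532	0.0052658
534	0.0051817
536	0.00510011
538	0.00502094
540	0.00494414
542	0.00486961
544	0.00479731
546	0.00472716
548	0.00465909
550	0.00459305
552	0.00452898
554	0.00446681
556	0.00440649
558	0.00434797
560	0.00429119
562	0.0042361
564	0.00418265
566	0.00413079
568	0.00408047
570	0.00403165
572	0.00398428
574	0.00393833
576	0.00389374
578	0.00385047
580	0.0038085
582	0.00376777
584	0.00372826
586	0.00368992
588	0.00365272
590	0.00361663
592	0.00358162
594	0.00354764
596	0.00351468
598	0.0034827
600	0.00345167
602	0.00342156
604	0.00339235
606	0.00336401
608	0.00333651
610	0.00330983
612	0.00328394
614	0.00325883
616	0.00323446
618	0.00321082
620	0.00318788
622	0.00316562
624	0.00314403
626	0.00312308
628	0.00310275
630	0.00308302
632	0.00306389
634	0.00304532
636	0.00302731
638	0.00300983
640	0.00299287
642	0.00297642
644	0.00296045
646	0.00294497
648	0.00292994
650	0.00291536
652	0.00290121
654	0.00288749
656	0.00287417
658	0.00286125
660	0.00284871
662	0.00283655
664	0.00282475
666	0.0028133
668	0.00280219
670	0.00279141
672	0.00278095
674	0.00277081
676	0.00276096
678	0.00275141
680	0.00274214
682	0.00273315
684	0.00272443
686	0.00271596
688	0.00270775
690	0.00269978
692	0.00269205
694	0.00268455
696	0.00267727
698	0.00267021
700	0.00266336
702	0.00265671
704	0.00265026
706	0.00264401
708	0.00263793
710	0.00263204
712	0.00262633
714	0.00262078
716	0.0026154
718	0.00261018
720	0.00260512
722	0.00260021
724	0.00259544
726	0.00259081
728	0.00258632
730	0.00258197
732	0.00257774
734	0.00257364
736	0.00256967
738	0.00256581
740	0.00256206
742	0.00255843
744	0.00255491
746	0.00255149
748	0.00254817
750	0.00254495
752	0.00254183
754	0.0025388
756	0.00253586
758	0.002533
760	0.00253024
762	0.00252755
764	0.00252495
766	0.00252242
768	0.00251997
770	0.00251759
772	0.00251528
774	0.00251304
776	0.00251086
778	0.00250875
780	0.00250671
782	0.00250472
784	0.0025028
786	0.00250093
788	0.00249911
790	0.00249736
792	0.00249565
794	0.00249399
796	0.00249239
798	0.00249083
800	0.00248931
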