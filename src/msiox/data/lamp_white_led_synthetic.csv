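# Synthetic white-LED emission spectrum (relative irradiance)
# wavelength_nm,value
398.0,0.0146852
399.0,0.0149744
400.0,0.0152799
401.0,0.0156029
402.0,0.0159446
403.0,0.0163065
404.0,0.0166908
405.0,0.0171
406.0,0.0175376
407.0,0.0180083
408.0,0.0185185
409.0,0.0190769
410.0,0.0196953
411.0,0.0203898
412.0,0.0211821
413.0,0.022101
414.0,0.0231845
415.0,0.0244822
416.0,0.0260583
417.0,0.0279943
418.0,0.0303926
419.0,0.0333798
420.0,0.0371103
421.0,0.0417693
422.0,0.047575
423.0,0.0547804
424.0,0.0636726
425.0,0.0745706
426.0,0.0878207
427.0,0.103789
428.0,0.122849
429.0,0.145371
430.0,0.171697
431.0,0.20213
432.0,0.2369
433.0,0.276148
434.0,0.319895
435.0,0.368024
436.0,0.420255
437.0,0.476134
438.0,0.535024
439.0,0.596105
440.0,0.658386
441.0,0.720723
442.0,0.781855
443.0,0.84044
444.0,0.895108
445.0,0.944509
446.0,0.987378
447.0,1.02259
448.0,1.04919
449.0,1.06649
450.0,1.07404
451.0,1.0717
452.0,1.05962
453.0,1.03823
454.0,1.00825
455.0,0.97062
456.0,0.926471
457.0,0.877074
458.0,0.823778
459.0,0.767958
460.0,0.710957
461.0,0.65404
462.0,0.598352
463.0,0.544888
464.0,0.494468
465.0,0.447734
466.0,0.40514
467.0,0.366969
468.0,0.33334
469.0,0.304234
470.0,0.279511
471.0,0.258941
472.0,0.242227
473.0,0.229024
474.0,0.218965
475.0,0.211677
476.0,0.206794
477.0,0.203972
478.0,0.202892
479.0,0.203267
480.0,0.204845
481.0,0.207406
482.0,0.210768
483.0,0.214773
484.0,0.219296
485.0,0.224234
486.0,0.229503
487.0,0.23504
488.0,0.240794
489.0,0.246725
490.0,0.252802
491.0,0.259003
492.0,0.26531
493.0,0.271709
494.0,0.278188
495.0,0.28474
496.0,0.291357
497.0,0.298032
498.0,0.304761
499.0,0.311538
500.0,0.318358
501.0,0.325217
502.0,0.33211
503.0,0.339032
504.0,0.345979
505.0,0.352946
506.0,0.359929
507.0,0.366921
508.0,0.373918
509.0,0.380916
510.0,0.387908
511.0,0.39489
512.0,0.401856
513.0,0.4088
514.0,0.415718
515.0,0.422602
516.0,0.429449
517.0,0.436251
518.0,0.443004
519.0,0.449701
520.0,0.456336
521.0,0.462904
522.0,0.469398
523.0,0.475814
524.0,0.482144
525.0,0.488384
526.0,0.494527
527.0,0.500567
528.0,0.506499
529.0,0.512316
530.0,0.518014
531.0,0.523587
532.0,0.529029
533.0,0.534334
534.0,0.539498
535.0,0.544515
536.0,0.54938
537.0,0.554088
538.0,0.558635
539.0,0.563014
540.0,0.567223
541.0,0.571256
542.0,0.575109
543.0,0.578778
544.0,0.582259
545.0,0.585549
546.0,0.588644
547.0,0.59154
548.0,0.594234
549.0,0.596725
550.0,0.599007
551.0,0.60108
552.0,0.602941
553.0,0.604588
554.0,0.606019
555.0,0.607233
556.0,0.608227
557.0,0.609002
558.0,0.609556
559.0,0.609889
560.0,0.61
561.0,0.609889
562.0,0.609556
563.0,0.609002
564.0,0.608227
565.0,0.607233
566.0,0.606019
567.0,0.604588
568.0,0.602941
569.0,0.60108
570.0,0.599007
571.0,0.596725
572.0,0.594234
573.0,0.59154
574.0,0.588644
575.0,0.585549
576.0,0.582259
577.0,0.578778
578.0,0.575109
579.0,0.571256
580.0,0.567223
581.0,0.563014
582.0,0.558635
583.0,0.554088
584.0,0.54938
585.0,0.544515
586.0,0.539498
587.0,0.534334
588.0,0.529029
589.0,0.523587
590.0,0.518014
591.0,0.512316
592.0,0.506499
593.0,0.500567
594.0,0.494527
595.0,0.488384
596.0,0.482144
597.0,0.475814
598.0,0.469398
599.0,0.462904
600.0,0.456336
601.0,0.449701
602.0,0.443004
603.0,0.436251
604.0,0.429449
605.0,0.422602
606.0,0.415718
607.0,0.4088
608.0,0.401856
609.0,0.39489
610.0,0.387908
611.0,0.380916
612.0,0.373918
613.0,0.366921
614.0,0.359928
615.0,0.352946
616.0,0.345979
617.0,0.339031
618.0,0.332108
619.0,0.325215
620.0,0.318354
621.0,0.311532
622.0,0.304751
623.0,0.298016
624.0,0.291331
625.0,0.2847
626.0,0.278126
627.0,0.271612
628.0,0.265162
629.0,0.25878
630.0,0.252467
631.0,0.246227
632.0,0.240062
633.0,0.233976
634.0,0.22797
635.0,0.222046
636.0,0.216207
637.0,0.210455
638.0,0.204791
639.0,0.199218
640.0,0.193736
641.0,0.188346
642.0,0.183051
643.0,0.177851
644.0,0.172747
645.0,0.16774
646.0,0.16283
647.0,0.158018
648.0,0.153305
649.0,0.148691
650.0,0.144175
651.0,0.139759
652.0,0.135442
653.0,0.131223
654.0,0.127103
655.0,0.123081
656.0,0.119157
657.0,0.11533
658.0,0.1116
659.0,0.107965
660.0,0.104426
661.0,0.100981
662.0,0.0976291
663.0,0.0943695
664.0,0.0912012
665.0,0.0881229
666.0,0.0851335
667.0,0.0822318
668.0,0.0794165
669.0,0.0766863
670.0,0.0740397
671.0,0.0714755
672.0,0.0689921
673.0,0.0665881
674.0,0.0642619
675.0,0.0620122
676.0,0.0598373
677.0,0.0577357
678.0,0.0557058
679.0,0.0537461
680.0,0.0518549
681.0,0.0500306
682.0,0.0482717
683.0,0.0465766
684.0,0.0449436
685.0,0.0433711
686.0,0.0418577
687.0,0.0404016
688.0,0.0390014
689.0,0.0376554
690.0,0.0363622
691.0,0.0351201
692.0,0.0339277
693.0,0.0327835
694.0,0.0316859
695.0,0.0306336
696.0,0.0296251
697.0,0.028659
698.0,0.0277339
699.0,0.0268485
700.0,0.0260013
701.0,0.0251911
702.0,0.0244166
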