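# Synthetic stand-in tabulation of deoxygenated hemoglobin molar extinction (cm^-1/M)
# wavelength_nm,epsilon
398.0,180000
399.0,203633
400.0,223000
401.0,234508
402.0,244646
403.0,253541
404.0,261392
405.0,268455
406.0,275035
407.0,281478
408.0,288166
409.0,295519
410.0,304000
411.0,313401
412.0,323167
413.0,333285
414.0,343737
415.0,354501
416.0,365553
417.0,376865
418.0,388404
419.0,400134
420.0,412011
421.0,423990
422.0,436019
423.0,448043
424.0,460000
425.0,473280
426.0,488309
427.0,503436
428.0,516798
429.0,526356
430.0,530000
431.0,527140
432.0,519514
433.0,508592
434.0,495819
435.0,482547
436.0,470000
437.0,458256
438.0,445679
439.0,430961
440.0,413000
441.0,384539
442.0,343930
443.0,298302
444.0,253288
445.0,212551
446.0,177957
447.0,150068
448.0,128677
449.0,113257
450.0,103300
451.0,96574.2
452.0,90985.1
453.0,86416.9
454.0,82778
455.0,80000
456.0,77941.1
457.0,76334.6
458.0,74958.7
459.0,73610.1
460.0,72100
461.0,70352.4
462.0,68460.7
463.0,66497.6
464.0,64529.5
465.0,62615.3
466.0,60807.6
467.0,59152.6
468.0,57691.5
469.0,56462.1
470.0,55500
471.0,54754.7
472.0,54130.9
473.0,53597.7
474.0,53126.3
475.0,52688.6
476.0,52257.9
477.0,51808.2
478.0,51314.4
479.0,50752.6
480.0,50100
481.0,49364.4
482.0,48567.2
483.0,47707.6
484.0,46785.6
485.0,45801.3
486.0,44755.9
487.0,43650.7
488.0,42487.8
489.0,41269.8
490.0,40000
491.0,38434.3
492.0,36457
493.0,34253.8
494.0,31986.2
495.0,29785.4
496.0,27752
497.0,25959.5
498.0,24460.8
499.0,23295.9
500.0,22500
501.0,21906.8
502.0,21361.3
503.0,20913.9
504.0,20611.5
505.0,20500
506.0,20903.8
507.0,21936.2
508.0,23326.5
509.0,24749.9
510.0,25800
511.0,26470.2
512.0,27066.1
513.0,27600.2
514.0,28086.8
515.0,28542.2
516.0,28983.5
517.0,29429.5
518.0,29900
519.0,30415.9
520.0,31000
521.0,31652.5
522.0,32353.6
523.0,33097.2
524.0,33876
525.0,34682.5
526.0,35508.2
527.0,36343.5
528.0,37178.2
529.0,38001.1
530.0,38800
531.0,39573.5
532.0,40331.9
533.0,41080.6
534.0,41825.3
535.0,42572.5
536.0,43328.8
537.0,44101.7
538.0,44898.8
539.0,45728.6
540.0,46600
541.0,47588.6
542.0,48692.4
543.0,49796.9
544.0,50777.3
545.0,51500
546.0,52004.1
547.0,52430.5
548.0,52794.5
549.0,53112.1
550.0,53400
551.0,53692.4
552.0,53987.1
553.0,54246
554.0,54430
555.0,54500
556.0,54465.1
557.0,54367.1
558.0,54216.7
559.0,54024.1
560.0,53800
561.0,53382.4
562.0,52680.2
563.0,51809.4
564.0,50881.1
565.0,50000
566.0,49161.6
567.0,48294.2
568.0,47395.8
569.0,46464.8
570.0,45500
571.0,44498.4
572.0,43462.6
573.0,42399.4
574.0,41315.4
575.0,40217.1
576.0,39110.1
577.0,38000
578.0,36853.3
579.0,35657.4
580.0,34446.4
581.0,33250.6
582.0,32096.2
583.0,31006.2
584.0,30000
585.0,29100.5
586.0,28285
587.0,27506.6
588.0,26723.5
589.0,25898.7
590.0,25000
591.0,23998.3
592.0,22910.4
593.0,21774.6
594.0,20624.7
595.0,19489.3
596.0,18392.2
597.0,17352.1
598.0,16383.3
599.0,15496.7
600.0,14700
601.0,13957.3
602.0,13235.8
603.0,12544.9
604.0,11891.9
605.0,11282.5
606.0,10720.8
607.0,10209.9
608.0,9751.91
609.0,9348.23
610.0,9000
611.0,8690.88
612.0,8402.54
613.0,8133.19
614.0,7881.17
615.0,7645
616.0,7423.31
617.0,7214.87
618.0,7018.54
619.0,6833.29
620.0,6658.15
621.0,6492.25
622.0,6334.79
623.0,6185.02
624.0,6042.25
625.0,5905.85
626.0,5775.22
627.0,5649.81
628.0,5529.11
629.0,5412.66
630.0,5300
631.0,5191.88
632.0,5089.03
633.0,4991
634.0,4897.38
635.0,4807.81
636.0,4721.91
637.0,4639.36
638.0,4559.85
639.0,4483.07
640.0,4408.75
641.0,4336.63
642.0,4266.46
643.0,4198.01
644.0,4131.06
645.0,4065.4
646.0,4000.83
647.0,3937.18
648.0,3874.26
649.0,3811.92
650.0,3750
651.0,3688.95
652.0,3629.28
653.0,3571
654.0,3514.07
655.0,3458.48
656.0,3404.21
657.0,3351.25
658.0,3299.57
659.0,3249.16
660.0,3200
661.0,3152.07
662.0,3105.3
663.0,3059.64
664.0,3015.02
665.0,2971.37
666.0,2928.65
667.0,2886.78
668.0,2845.73
669.0,2805.43
670.0,2765.85
671.0,2726.94
672.0,2688.64
673.0,2650.92
674.0,2613.75
675.0,2577.07
676.0,2540.86
677.0,2505.08
678.0,2469.7
679.0,2434.68
680.0,2400
681.0,2364.55
682.0,2327.56
683.0,2289.47
684.0,2250.72
685.0,2211.69
686.0,2172.78
687.0,2134.32
688.0,2096.66
689.0,2060.09
690.0,2024.9
691.0,1991.35
692.0,1959.68
693.0,1930.14
694.0,1902.92
695.0,1878.24
696.0,1856.31
697.0,1837.31
698.0,1821.46
699.0,1808.95
700.0,1800
701.0,1794
702.0,1790
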