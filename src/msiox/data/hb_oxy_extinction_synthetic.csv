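# Synthetic stand-in tabulation of oxygenated hemoglobin molar extinction (cm^-1/M)
# wavelength_nm,epsilon
398.0,230000
399.0,248653
400.0,266000
401.0,280973
402.0,295012
403.0,308450
404.0,321724
405.0,335365
406.0,350000
407.0,367238
408.0,387573
409.0,409875
410.0,432715
411.0,454327
412.0,472623
413.0,485292
414.0,490000
415.0,489665
416.0,488706
417.0,487191
418.0,485188
419.0,482768
420.0,480000
421.0,471993
422.0,455198
423.0,431902
424.0,404429
425.0,374905
426.0,345123
427.0,316484
428.0,290004
429.0,266367
430.0,246000
431.0,227041
432.0,207996
433.0,189553
434.0,172218
435.0,156330
436.0,142091
437.0,129597
438.0,118869
439.0,109885
440.0,102600
441.0,96525.2
442.0,91127.1
443.0,86304.2
444.0,81971
445.0,78054.1
446.0,74491
447.0,71227.8
448.0,68217.8
449.0,65420.3
450.0,62800
451.0,60362.5
452.0,58116.1
453.0,56035.5
454.0,54098.2
455.0,52284.2
456.0,50575.6
457.0,48956.5
458.0,47412.5
459.0,45930.8
460.0,44500
461.0,43116.8
462.0,41786.4
463.0,40510.8
464.0,39291.4
465.0,38129.4
466.0,37025.5
467.0,35980.4
468.0,34994.3
469.0,34067.5
470.0,33200
471.0,32371.2
472.0,31565.2
473.0,30788.6
474.0,30047.2
475.0,29346.2
476.0,28690.4
477.0,28084.1
478.0,27531.1
479.0,27035.3
480.0,26600
481.0,26218
482.0,25874.4
483.0,25561.9
484.0,25273.5
485.0,25002.7
486.0,24743.1
487.0,24488.7
488.0,24233.7
489.0,23972.6
490.0,23700
491.0,23409.6
492.0,23103.9
493.0,22791
494.0,22478.6
495.0,22174.1
496.0,21884.3
497.0,21615.9
498.0,21375
499.0,21167.7
500.0,21000
501.0,20853.6
502.0,20708.6
503.0,20568.5
504.0,20436.8
505.0,20316.6
506.0,20211.1
507.0,20123.5
508.0,20057.1
509.0,20014.8
510.0,20000
511.0,20057.8
512.0,20223.4
513.0,20486
514.0,20835.9
515.0,21263.5
516.0,21759
517.0,22312.2
518.0,22911.9
519.0,23545.8
520.0,24200
521.0,24986.6
522.0,26013.4
523.0,27258.8
524.0,28698.2
525.0,30301.3
526.0,32029.2
527.0,33832.2
528.0,35647.6
529.0,37399.8
530.0,39000
531.0,40475.8
532.0,41916.7
533.0,43319.5
534.0,44681.3
535.0,46000
536.0,47405.6
537.0,48960.6
538.0,50551.2
539.0,52048.3
540.0,53308.2
541.0,54177.2
542.0,54500
543.0,54292.9
544.0,53737.1
545.0,52932.9
546.0,51979.8
547.0,50972.6
548.0,50000
549.0,49004.3
550.0,47886.2
551.0,46666.2
552.0,45364.4
553.0,44000
554.0,42282.7
555.0,40145.7
556.0,37910.5
557.0,35842.7
558.0,34153.8
559.0,33018.1
560.0,32600
561.0,32694.8
562.0,32959.7
563.0,33367.2
564.0,33889.8
565.0,34500
566.0,35653.8
567.0,37632.3
568.0,40124.8
569.0,42745.2
570.0,45000
571.0,47015.5
572.0,49214.8
573.0,51452.7
574.0,53556.3
575.0,55326.6
576.0,56547.3
577.0,57000
578.0,56306.2
579.0,54438.7
580.0,51747.8
581.0,48581.3
582.0,45248.2
583.0,42000
584.0,38251.5
585.0,33742.2
586.0,29073.1
587.0,24675.9
588.0,20805.9
589.0,17575.3
590.0,15000
591.0,12861.9
592.0,10970.1
593.0,9325.03
594.0,7915.19
595.0,6721.77
596.0,5722.12
597.0,4892.39
598.0,4209.34
599.0,3651.55
600.0,3200
601.0,2823.35
602.0,2497.28
603.0,2215.73
604.0,1973.21
605.0,1764.81
606.0,1586.16
607.0,1433.45
608.0,1303.35
609.0,1193.01
610.0,1100
611.0,1018.77
612.0,945.143
613.0,878.95
614.0,819.937
615.0,767.809
616.0,722.25
617.0,682.949
618.0,649.625
619.0,622.035
620.0,600
621.0,581.519
622.0,564.566
623.0,548.991
624.0,534.658
625.0,521.444
626.0,509.238
627.0,497.939
628.0,487.457
629.0,477.705
630.0,468.607
631.0,460.09
632.0,452.09
633.0,444.543
634.0,437.393
635.0,430.584
636.0,424.068
637.0,417.795
638.0,411.72
639.0,405.802
640.0,400
641.0,394.327
642.0,388.825
643.0,383.494
644.0,378.336
645.0,373.352
646.0,368.543
647.0,363.909
648.0,359.452
649.0,355.172
650.0,351.07
651.0,347.147
652.0,343.403
653.0,339.839
654.0,336.456
655.0,333.254
656.0,330.234
657.0,327.398
658.0,324.746
659.0,322.28
660.0,320
661.0,317.806
662.0,315.607
663.0,313.417
664.0,311.25
665.0,309.12
666.0,307.039
667.0,305.022
668.0,303.08
669.0,301.227
670.0,299.473
671.0,297.831
672.0,296.313
673.0,294.93
674.0,293.694
675.0,292.615
676.0,291.706
677.0,290.978
678.0,290.443
679.0,290.113
680.0,290
681.0,290
682.0,290
683.0,290
684.0,290
685.0,290
686.0,290
687.0,290
688.0,290
689.0,290
690.0,290
691.0,290
692.0,290
693.0,290
694.0,290
695.0,290
696.0,290
697.0,290
698.0,290
699.0,290
700.0,290
701.0,290
702.0,290
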