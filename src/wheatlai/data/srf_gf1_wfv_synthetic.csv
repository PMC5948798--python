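wavelength_nm,b1,b2,b3,b4
400,0,0,0,0
402,0,0,0,0
404,0,0,0,0
406,0,0,0,0
408,0,0,0,0
410,0,0,0,0
412,0,0,0,0
414,0,0,0,0
416,0,0,0,0
418,0,0,0,0
420,0.00100984,0,0,0
422,0.00153381,0,0,0
424,0.00229941,0,0,0
426,0.00340243,0,0,0
428,0.00496923,0,0,0
430,0.00716336,0,0,0
432,0.0101923,0,0,0
434,0.0143138,0,0,0
436,0.0198411,0,0,0
438,0.0271459,0,0,0
440,0.036658,0,0,0
442,0.048861,0,0,0
444,0.0642811,0,0,0
446,0.0834702,0,0,0
448,0.106981,0,0,0
450,0.135335,0,0,0
452,0.168983,0,0,0
454,0.208258,0,0,0
456,0.25333,0,0,0
458,0.304159,0,0,0
460,0.360448,0,0,0
462,0.42161,0,0,0
464,0.486752,0,0,0
466,0.554667,0,0,0
468,0.623855,0,0,0
470,0.692569,0,0,0
472,0.758875,0,0,0
474,0.820738,0,0,0
476,0.876126,0,0,0
478,0.923116,0,0,0
480,0.960005,0,0,0
482,0.985414,0,0,0
484,0.998369,0,0,0
486,0.998369,0,0,0
488,0.985414,0,0,0
490,0.960005,0.00100984,0,0
492,0.923116,0.00153381,0,0
494,0.876126,0.00229941,0,0
496,0.820738,0.00340243,0,0
498,0.758875,0.00496923,0,0
500,0.692569,0.00716336,0,0
502,0.623855,0.0101923,0,0
504,0.554667,0.0143138,0,0
506,0.486752,0.0198411,0,0
508,0.42161,0.0271459,0,0
510,0.360448,0.036658,0,0
512,0.304159,0.048861,0,0
514,0.25333,0.0642811,0,0
516,0.208258,0.0834702,0,0
518,0.168983,0.106981,0,0
520,0.135335,0.135335,0,0
522,0.106981,0.168983,0,0
524,0.0834702,0.208258,0,0
526,0.0642811,0.25333,0,0
528,0.048861,0.304159,0,0
530,0.036658,0.360448,0,0
532,0.0271459,0.42161,0,0
534,0.0198411,0.486752,0,0
536,0.0143138,0.554667,0,0
538,0.0101923,0.623855,0,0
540,0.00716336,0.692569,0,0
542,0.00496923,0.758875,0,0
544,0.00340243,0.820738,0,0
546,0.00229941,0.876126,0,0
548,0.00153381,0.923116,0,0
550,0.00100984,0.960005,0,0
552,0,0.985414,0,0
554,0,0.998369,0,0
556,0,0.998369,0,0
558,0,0.985414,0,0
560,0,0.960005,0,0
562,0,0.923116,0,0
564,0,0.876126,0,0
566,0,0.820738,0,0
568,0,0.758875,0,0
570,0,0.692569,0,0
572,0,0.623855,0,0
574,0,0.554667,0,0
576,0,0.486752,0,0
578,0,0.42161,0,0
580,0,0.360448,0,0
582,0,0.304159,0,0
584,0,0.25333,0,0
586,0,0.208258,0,0
588,0,0.168983,0,0
590,0,0.135335,0,0
592,0,0.106981,0,0
594,0,0.0834702,0,0
596,0,0.0642811,0,0
598,0,0.048861,0,0
600,0,0.036658,0,0
602,0,0.0271459,0,0
604,0,0.0198411,0,0
606,0,0.0143138,0.00153381,0
608,0,0.0101923,0.00245682,0
610,0,0.00716336,0.00386592,0
612,0,0.00496923,0.00597602,0
614,0,0.00340243,0.00907509,0
616,0,0.00229941,0.0135384,0
618,0,0.00153381,0.0198411,0
620,0,0.00100984,0.0285655,0
622,0,0,0.0404015,0
624,0,0,0.0561348,0
626,0,0,0.0766206,0
628,0,0,0.10274,0
630,0,0,0.135335,0
632,0,0,0.175131,0
634,0,0,0.222635,0
636,0,0,0.278037,0
638,0,0,0.341108,0
640,0,0,0.411112,0
642,0,0,0.486752,0
644,0,0,0.566154,0
646,0,0,0.646905,0
648,0,0,0.726149,0
650,0,0,0.800737,0
652,0,0,0.867428,0
654,0,0,0.923116,0
656,0,0,0.965069,0
658,0,0,0.991151,0
660,0,0,1,0
662,0,0,0.991151,0
664,0,0,0.965069,0
666,0,0,0.923116,0
668,0,0,0.867428,0
670,0,0,0.800737,0
672,0,0,0.726149,0
674,0,0,0.646905,0
676,0,0,0.566154,0
678,0,0,0.486752,0
680,0,0,0.411112,0
682,0,0,0.341108,0
684,0,0,0.278037,0
686,0,0,0.222635,0
688,0,0,0.175131,0
690,0,0,0.135335,0
692,0,0,0.10274,0
694,0,0,0.0766206,0
696,0,0,0.0561348,0
698,0,0,0.0404015,0
700,0,0,0.0285655,0
702,0,0,0.0198411,0
704,0,0,0.0135384,0
706,0,0,0.00907509,0
708,0,0,0.00597602,0
710,0,0,0.00386592,0
712,0,0,0.00245682,0
714,0,0,0.00153381,0
716,0,0,0,0
718,0,0,0,0
720,0,0,0,0.00120386
722,0,0,0,0.00153381
724,0,0,0,0.00194553
726,0,0,0,0.00245682
728,0,0,0,0.00308872
730,0,0,0,0.00386592
732,0,0,0,0.00481723
734,0,0,0,0.00597602
736,0,0,0,0.00738068
738,0,0,0,0.00907509
740,0,0,0,0.011109
742,0,0,0,0.0135384
744,0,0,0,0.016426
746,0,0,0,0.0198411
748,0,0,0,0.0238599
750,0,0,0,0.0285655
752,0,0,0,0.0340475
754,0,0,0,0.0404015
756,0,0,0,0.0477287
758,0,0,0,0.0561348
760,0,0,0,0.0657285
762,0,0,0,0.0766206
764,0,0,0,0.0889216
766,0,0,0,0.10274
768,0,0,0,0.118179
770,0,0,0,0.135335
772,0,0,0,0.154295
774,0,0,0,0.175131
776,0,0,0,0.197899
778,0,0,0,0.222635
780,0,0,0,0.249352
782,0,0,0,0.278037
784,0,0,0,0.308647
786,0,0,0,0.341108
788,0,0,0,0.375311
790,0,0,0,0.411112
792,0,0,0,0.448332
794,0,0,0,0.486752
796,0,0,0,0.526122
798,0,0,0,0.566154
800,0,0,0,0.606531
802,0,0,0,0.646905
804,0,0,0,0.686908
806,0,0,0,0.726149
808,0,0,0,0.764228
810,0,0,0,0.800737
812,0,0,0,0.83527
814,0,0,0,0.867428
816,0,0,0,0.89683
818,0,0,0,0.923116
820,0,0,0,0.945959
822,0,0,0,0.965069
824,0,0,0,0.980199
826,0,0,0,0.991151
828,0,0,0,0.99778
830,0,0,0,1
832,0,0,0,0.99778
834,0,0,0,0.991151
836,0,0,0,0.980199
838,0,0,0,0.965069
840,0,0,0,0.945959
842,0,0,0,0.923116
844,0,0,0,0.89683
846,0,0,0,0.867428
848,0,0,0,0.83527
850,0,0,0,0.800737
852,0,0,0,0.764228
854,0,0,0,0.726149
856,0,0,0,0.686908
858,0,0,0,0.646905
860,0,0,0,0.606531
862,0,0,0,0.566154
864,0,0,0,0.526122
866,0,0,0,0.486752
868,0,0,0,0.448332
870,0,0,0,0.411112
872,0,0,0,0.375311
874,0,0,0,0.341108
876,0,0,0,0.308647
878,0,0,0,0.278037
880,0,0,0,0.249352
882,0,0,0,0.222635
884,0,0,0,0.197899
886,0,0,0,0.175131
888,0,0,0,0.154295
890,0,0,0,0.135335
892,0,0,0,0.118179
894,0,0,0,0.10274
896,0,0,0,0.0889216
898,0,0,0,0.0766206
900,0,0,0,0.0657285
902,0,0,0,0.0561348
904,0,0,0,0.0477287
906,0,0,0,0.0404015
908,0,0,0,0.0340475
910,0,0,0,0.0285655
912,0,0,0,0.0238599
914,0,0,0,0.0198411
916,0,0,0,0.016426
918,0,0,0,0.0135384
920,0,0,0,0.011109
922,0,0,0,0.00907509
924,0,0,0,0.00738068
926,0,0,0,0.00597602
928,0,0,0,0.00481723
930,0,0,0,0.00386592
932,0,0,0,0.00308872
934,0,0,0,0.00245682
936,0,0,0,0.00194553
938,0,0,0,0.00153381
940,0,0,0,0.00120386
942,0,0,0,0
944,0,0,0,0
946,0,0,0,0
948,0,0,0,0
950,0,0,0,0
952,0,0,0,0
954,0,0,0,0
956,0,0,0,0
958,0,0,0,0
960,0,0,0,0
962,0,0,0,0
964,0,0,0,0
966,0,0,0,0
968,0,0,0,0
970,0,0,0,0
972,0,0,0,0
974,0,0,0,0
976,0,0,0,0
978,0,0,0,0
980,0,0,0,0
982,0,0,0,0
984,0,0,0,0
986,0,0,0,0
988,0,0,0,0
990,0,0,0,0
992,0,0,0,0
994,0,0,0,0
996,0,0,0,0
998,0,0,0,0
1000,0,0,0,0
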