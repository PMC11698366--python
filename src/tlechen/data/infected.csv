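infected
1024
1746
2585
3045
3168
3575
3068
3460
4778
4652
5362
5499
5628
5281
5477
5505
5873
5928
5591
4884
4608
4535
4838
4541
4526
4738
4474
3913
3669
4211
3861
4092
3852
3555
3013
3260
3747
3330
3162
2866
2523
1726
2136
2227
1982
1793
1569
1376
997
1031
1052
841
627
677
664
537
632
653
563
476
407
363
283
317
279
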