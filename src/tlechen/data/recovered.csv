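recovered
298
341
375
424
608
817
793
843
893
2051
2499
2978
3511
2996
3405
4349
4535
4981
5238
6090
4622
5072
6296
5212
5772
4973
4445
4284
4375
5162
4377
4604
4638
4023
4824
3878
4083
3464
4088
3379
3825
2983
2983
3469
3372
3207
2847
2596
1928
2136
2036
1922
1880
1585
1409
1085
995
1081
839
719
685
559
525
668
645
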