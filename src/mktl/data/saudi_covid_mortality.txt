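# Saudi Arabia COVID-19 daily mortality rates, 4-30 August 2021 (27 values)
0.2113
0.2683
0.2487
0.2674
0.1716
0.2666
0.2091
0.2278
0.1706
0.2271
0.1890
0.2077
0.2452
0.1319
0.2259
0.1504
0.1879
0.1689
0.2063
0.2249
0.1686
0.1310
0.1497
0.1309
0.1495
0.1121
0.1120
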