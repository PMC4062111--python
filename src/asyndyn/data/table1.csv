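day,monomers,dimers,oligomers
1,2605,22,108
2,2106,18,139
3,1697,22,154
4,1277,33,140
5,1030,37,151
6,1318,54,153
7,1205,86,197
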