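>MA0150.1	NFE2L2
A  [ 10  0  0 20  0  6  5 16  0  0 15 ]
C  [  1  0  0  0 17  2 10  0  0 20  2 ]
G  [  9  0 19  0  1  1  1  2 20  0  2 ]
T  [  0 20  1  0  2 11  4  2  0  0  1 ]
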