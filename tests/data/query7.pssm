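
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
            A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
    1 M    -1  5  0 -2 -3  1  0 -2  0 -3 -2  4 -1 -3 -1  0 -1 -3 -2 -2   0  38  0  0  0  6  0  0  0  0  0 50  0  0  0  6  0  0  0  0  0.45 0.12
    2 K    -1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2   4  11  0  0  0  6  9  0  0  0  0 64  0  0  0  6  0  0  0  0  0.52 0.16
    3 A     4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0  74  0  0  0  2  0  0  4  0  2  2  0  0  0  0 12  4  0  0  0  0.30 0.14
    4 X     0 -1 -1 -1 -2 -1 -1 -1 -1 -1 -1 -1 -1 -1 -2  0  0 -2 -1 -1   5  5  5  5  5  5  5  5  5  5  5  5  5  5  5  5  5  5  5  5  0.01 0.02
    5 G     0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3   6  0  2  0  0  0  0 84  0  0  0  0  0  0  0  6  0  0  0  2  1.10 0.21
    6 W    -3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3   0  0  0  0  0  0  0  0  0  0  4  0  0  4  0  0  0 88  4  0  2.30 0.25
    7 V     0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4   4  0  0  0  2  0  0  0  0 20 11  0  4  2  0  0  4  0  2 51  0.41 0.18

                      K         Lambda
Standard Ungapped    0.1352    0.3176
Standard Gapped      0.0410    0.2670
PSI Ungapped         0.1623    0.3136
PSI Gapped           0.0408    0.2670
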