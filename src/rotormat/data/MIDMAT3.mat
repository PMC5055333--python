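# MIDMAT3 reference substitution matrix (verbatim published values)
# Amino acid order: A R N D C Q E G H I L K M F P S T W Y V
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A  9 -1  1  1  2  0  0 -2  1 -1 -1 -1  0  1 -3  3  2  1  1  1
R -1 12 -1 -1  1  5  5 -4  2  2  1  6  5  0 -7  0  0  0  1 -1
N  1 -1 11  5  3  0 -1 -1  3 -3 -1  0  0  2 -7  3  1  2  2  0
D  1 -1  5 11  4  0 -1 -2  3 -3 -1 -1  0  3 -6  3  2  3  2  0
C  2  1  3  4 11  1  1 -2  4 -1  0  1  1  3 -5  5  4  4  3  2
Q  0  5  0  0  1 12  6 -4  3  2  2  6  5  1 -6  1  0  0  1  0
E  0  5 -1 -1  1  6 12 -4  2  2  1  5  5  1 -6  0  0  0  1  0
G -2 -4 -1 -2 -2 -4 -4  5 -3 -7 -6 -4 -4 -4 -8 -1 -3 -4 -4 -5
H  1  2  3  3  4  3  2 -3 10  0  0  2  3  4 -6  3  2  3  4  1
I -1  2 -3 -3 -1  2  2 -7  0  9  1  2  3  0 -6 -1  0 -1  0  0
L -1  1 -1 -1  0  2  1 -6  0  1  8  2  2  0 -6 -1 -1  0  0  0
K -1  6  0 -1  1  6  5 -4  2  2  2 12  5  1 -7  0  0  0  1  0
M  0  5  0  0  1  5  5 -4  3  3  2  5 12  2 -6  1  1  1  2  1
F  1  0  2  3  3  1  1 -4  4  0  0  1  2 12 -6  2  2  5  6  2
P -3 -7 -7 -6 -5 -6 -6 -8 -6 -6 -6 -7 -6 -6  3 -5 -4 -4 -6 -3
S  3  0  3  3  5  1  0 -1  3 -1 -1  0  1  2 -5 11  4  3  2  1
T  2  0  1  2  4  0  0 -3  2  0 -1  0  1  2 -4  4 10  3  2  2
W  1  0  2  3  4  0  0 -4  3 -1  0  0  1  5 -4  3  3 11  5  2
Y  1  1  2  2  3  1  1 -4  4  0  0  1  2  6 -6  2  2  5 12  2
V  1 -1  0  0  2  0  0 -5  1  0  0  0  1  2 -3  1  2  2  2  9
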