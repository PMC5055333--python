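# MIDMAT1 reference substitution matrix (verbatim published values)
# Amino acid order: A R N D C Q E G H I L K M F P S T W Y V
    A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
A   9  -2  -1   0   1  -2  -2  -1  -1  -3  -4  -3  -2  -1  -5   2   1  -1  -1   0
R  -2  15  -1  -1  -1   6   6  -6   2   3   2   7   6   0  -9  -1  -1   0   0  -2
N  -1  -1  13   6   3   0  -1  -2   3  -3  -2  -1   0   3  -9   2   1   3   3  -1
D   0  -1   6  13   3   0  -1  -3   3  -3  -2  -1   0   3  -8   3   2   4   2   0
C   1  -1   3   3  13   0  -1  -2   3  -1  -2  -1   0   2  -7   5   5   3   2   3
Q  -2   6   0   0   0  14   7  -5   3   3   2   7   6   1  -8   0  -1   1   1  -1
E  -2   6  -1  -1  -1   7  14  -6   2   3   2   6   6   1  -8  -1  -1   0   1  -2
G  -1  -6  -2  -3  -2  -5  -6   6  -4  -8  -8  -6  -6  -5 -10  -2  -4  -5  -5  -6
H  -1   2   3   3   3   3   2  -4  12   0  -1   2   3   5  -9   2   1   4   5   0
I  -3   3  -3  -3  -1   3   3  -8   0  11   1   3   4   0  -9  -2  -1  -1   0  -2
L  -4   2  -2  -2  -2   2   2  -8  -1   2  10   2   2  -1  -9  -3  -3  -2  -2  -2
K  -3   7  -1  -1  -1   7   6  -6   2   3   3  14   6   0  -9  -1  -2   0   0  -2
M  -2   6   0   0   0   6   6  -6   3   4   3   6  14   2  -8   0   0   1   2  -1
F  -1   0   3   3   3   1   0  -5   5   0  -1   0   2  15  -8   1   1   6   7   1
P  -4  -9  -9  -8  -7  -8  -8 -10  -9  -9  -9  -9  -8  -8   3  -7  -7  -7  -8  -6
S   2  -1   2   3   5   0  -1  -2   2  -2  -3  -1   0   2  -7  13   5   2   1   2
T   1  -1   1   2   5  -1  -1  -4   1  -1  -2  -2   0   1  -7   5  12   2   1   2
W   0   0   3   4   3   1   0  -5   4  -1  -2   0   1   6  -7   2   2  13   6   1
Y  -1   0   3   2   2   1   0  -5   5   0  -2   0   2   7  -8   1   1   6  15   1
V   0  -2  -1   0   3  -1  -1  -6   0  -2  -2  -2  -1   2  -6   2   2   2   1  10
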