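# MIDMAT2 reference substitution matrix (verbatim published values)
# Amino acid order: A R N D C Q E G H I L K M F P S T W Y V
    A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
A  10  -3  -1  -1   1  -2  -2  -2  -1  -4  -5  -3  -2  -2  -5   2   1  -1  -2   0
R  -1  14  -1  -1  -1   6   6  -6   2   2   2   7   5   0  -9  -1  -2  -1   0  -2
N   1  -1  13   5   3   0  -1  -3   3  -3  -2  -1   0   3  -9   2   1   3   2  -1
D   1  -1   5  12   3  -1  -1  -3   2  -3  -2  -1  -1   2  -8   2   1   3   2   0
C   2   0   4   4  12   0  -1  -3   2  -2  -2  -1   0   2  -8   5   4   2   2   2
Q   0   6   0  -1   1  13   6  -6   3   2   2   6   6   1  -9  -1  -1   0   1  -2
E   0   6  -1  -1   1   6  13  -6   2   3   2   6   6   0  -8  -1  -2   0   0  -2
G  -2  -4  -1  -2  -2  -4  -5   6  -4  -9  -9  -6  -6  -6 -11  -2  -4  -5  -6  -6
H   1   2   3   2   4   3   2  -3  12   0  -1   2   3   5  -9   1   1   4   5   0
I  -2   2  -3  -3  -1   2   3  -8   0  10   1   2   3  -1  -9  -3  -1  -1  -1  -2
L  -2   2  -2  -2  -1   2   2  -7  -1   1   9   2   2  -2  -9  -3  -3  -2  -2  -2
K  -1   7  -1  -1   1   6   6  -4   2   2   2  14   6   0  -9  -1  -2  -1   0  -2
M   0   5   0  -1   1   6   6  -5   3   3   2   6  13   1  -9  -1  -1   1   1  -1
F   0   0   3   2   4   1   0  -4   5  -1  -2   0   1  14  -9   1   1   6   7   1
P  -4  -9  -9  -8  -8  -9  -8 -10  -9  -9  -9  -9  -9  -8   2  -7  -7  -7  -9  -6
S   3   0   3   3   5   1   0  -1   3  -1  -2   0   1   2  -7  12   4   2   1   1
T   2  -1   2   2   4   0   0  -3   2   0  -2  -1   0   2  -7   4  12   2   1   1
W   1  -1   3   3   4   0   0  -4   4  -1  -2  -1   1   6  -7   3   3  13   6   1
Y   0   0   2   2   3   1   0  -4   5  -1  -2   0   1   7  -8   2   2   6  14   1
V   1  -1   0   0   2   0  -1  -6   1  -1  -1  -1   0   2  -6   1   1   2   2   9
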