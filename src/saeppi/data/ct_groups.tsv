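residue	group
A	1
G	1
V	1
I	2
L	2
F	2
P	2
Y	3
M	3
T	3
S	3
H	4
N	4
Q	4
W	4
R	5
K	5
D	6
E	6
C	7
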