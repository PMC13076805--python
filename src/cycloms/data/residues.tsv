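residue_code	monoisotopic_mass	average_mass
G	57.021464	57.0513
A	71.037114	71.0779
S	87.032028	87.0773
P	97.052764	97.1152
V	99.068414	99.1311
T	101.047679	101.1039
C	103.009185	103.1429
L	113.084064	113.1576
I	113.084064	113.1576
N	114.042927	114.1026
D	115.026943	115.0874
Q	128.058578	128.1292
K	128.094963	128.1723
E	129.042593	129.1155
M	131.040485	131.1961
H	137.058912	137.1393
F	147.068414	147.1739
R	156.101111	156.1857
Y	163.063329	163.1733
W	186.079313	186.2099
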