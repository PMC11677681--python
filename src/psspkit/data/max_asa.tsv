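# Maximum accessible surface area per residue type (A^2), theoretical
# values of Tien et al. 2013; X carries the mean of the 20 standard residues.
aa	max_asa
A	129.0
C	167.0
D	193.0
E	223.0
F	240.0
G	104.0
H	224.0
I	197.0
K	236.0
L	201.0
M	224.0
N	195.0
P	159.0
Q	225.0
R	274.0
S	155.0
T	172.0
V	174.0
W	285.0
Y	263.0
X	202.0
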