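# synthetic PPII propensity scale: constructed stand-in, rank-faithful
# to experimental host-guest polyproline-II trends; replaceable.
A	0.64
C	0.41
D	0.48
E	0.51
F	0.34
G	0.4
H	0.38
I	0.42
K	0.52
L	0.56
M	0.5
N	0.46
P	1.0
Q	0.66
R	0.62
S	0.54
T	0.44
V	0.39
W	0.3
Y	0.32
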