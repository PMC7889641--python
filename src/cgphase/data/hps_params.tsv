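res	mass	charge	sigma	lambda
A	71.08	0	0.504	0.730
R	156.20	1	0.656	0.000
N	114.10	0	0.568	0.432
D	115.10	-1	0.558	0.378
C	103.10	0	0.548	0.595
Q	128.10	0	0.602	0.514
E	129.10	-1	0.592	0.459
G	57.05	0	0.450	0.649
H	137.10	0	0.608	0.514
I	113.20	0	0.618	0.973
L	113.20	0	0.618	0.973
K	128.20	1	0.636	0.514
M	131.20	0	0.618	0.838
F	147.20	0	0.636	1.000
P	97.12	0	0.556	1.000
S	87.08	0	0.518	0.595
T	101.10	0	0.562	0.676
W	186.20	0	0.678	0.946
Y	163.20	0	0.646	0.865
V	99.07	0	0.586	0.892
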