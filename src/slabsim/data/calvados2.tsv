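code	sigma_nm	lambda	charge_e	mass_gmol
A	0.504	0.27432	0.0	71.0788
R	0.656	0.73076	1.0	156.1875
N	0.568	0.42558	0.0	114.1038
D	0.558	0.04160	-1.0	115.0886
C	0.548	0.56154	0.0	103.1388
Q	0.602	0.39343	0.0	128.1307
E	0.592	0.00069	-1.0	129.1155
G	0.450	0.70588	0.0	57.0519
H	0.608	0.46637	0.0	137.1411
I	0.618	0.54236	0.0	113.1594
L	0.618	0.64400	0.0	113.1594
K	0.636	0.17902	1.0	128.1741
M	0.618	0.53085	0.0	131.1926
F	0.636	0.86724	0.0	147.1766
P	0.556	0.35931	0.0	97.1167
S	0.518	0.46254	0.0	87.0782
T	0.562	0.37132	0.0	101.1051
W	0.678	0.98938	0.0	186.2132
Y	0.646	0.97746	0.0	163.1760
V	0.586	0.20838	0.0	99.1326
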