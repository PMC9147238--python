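label	descriptor	position	h1	c13
A	a-L-Fucp(4SO3-)-(1-	1	5.036	96.87
A	a-L-Fucp(4SO3-)-(1-	2	3.71	68.5
A	a-L-Fucp(4SO3-)-(1-	3	3.982	69.06
A	a-L-Fucp(4SO3-)-(1-	4	4.561	80.87
A	a-L-Fucp(4SO3-)-(1-	5	4.458	66.6
A	a-L-Fucp(4SO3-)-(1-	6	1.211	15.84
B	-3,4)-a-L-Fucp(2SO3-)-(1-	1	5.283	94.05
B	-3,4)-a-L-Fucp(2SO3-)-(1-	2	4.556	73.2
B	-3,4)-a-L-Fucp(2SO3-)-(1-	3	4.122	73.2
B	-3,4)-a-L-Fucp(2SO3-)-(1-	4	4.037	81.46
B	-3,4)-a-L-Fucp(2SO3-)-(1-	5	4.331	67.96
B	-3,4)-a-L-Fucp(2SO3-)-(1-	6	1.325	15.47
C	-3)-a-D-Fucp-(1-	1	4.995	99.81
C	-3)-a-D-Fucp-(1-	2	3.764	66.96
C	-3)-a-D-Fucp-(1-	3	3.858	75.67
C	-3)-a-D-Fucp-(1-	4	3.954	68.62
C	-3)-a-D-Fucp-(1-	5	4.25	66.7
C	-3)-a-D-Fucp-(1-	6	1.181	15.59
D	-3)-a-D-Fucp(4SO3-)-(1-	1	5.076	96.74
D	-3)-a-D-Fucp(4SO3-)-(1-	2	3.833	67.53
D	-3)-a-D-Fucp(4SO3-)-(1-	3	3.905	77.9
D	-3)-a-D-Fucp(4SO3-)-(1-	4	4.68	80.08
D	-3)-a-D-Fucp(4SO3-)-(1-	5	4.475	66.54
D	-3)-a-D-Fucp(4SO3-)-(1-	6	1.211	15.84
Ea	-3,4)-a-D-Fucp(2SO3-)-(1-	1	5.32	94.28
Ea	-3,4)-a-D-Fucp(2SO3-)-(1-	2	4.552	73.2
Ea	-3,4)-a-D-Fucp(2SO3-)-(1-	3	4.12	73.2
Ea	-3,4)-a-D-Fucp(2SO3-)-(1-	4	4.05	80.85
Ea	-3,4)-a-D-Fucp(2SO3-)-(1-	5	4.34	67.95
Ea	-3,4)-a-D-Fucp(2SO3-)-(1-	6	1.29	15.65
Eb	-3,4)-b-D-Fucp(2SO3-)-(1-	1	5.297	94.69
Eb	-3,4)-b-D-Fucp(2SO3-)-(1-	2	4.545	73.2
Eb	-3,4)-b-D-Fucp(2SO3-)-(1-	3	4.114	72.8
Eb	-3,4)-b-D-Fucp(2SO3-)-(1-	4	4.054	80.85
Eb	-3,4)-b-D-Fucp(2SO3-)-(1-	5	4.35	67.95
Eb	-3,4)-b-D-Fucp(2SO3-)-(1-	6	1.29	15.65
Fa	-3)-a-D-Fucp	1	5.161	92.25
Fa	-3)-a-D-Fucp	2	3.872	66.56
Fa	-3)-a-D-Fucp	3	3.871	75.36
Fa	-3)-a-D-Fucp	4	3.986	68.41
Fa	-3)-a-D-Fucp	5	4.118	66.07
Fa	-3)-a-D-Fucp	6	1.165	15.61
Fb	-3)-b-D-Fucp	1	4.517	96.25
Fb	-3)-b-D-Fucp	2	3.539	70.12
Fb	-3)-b-D-Fucp	3	3.633	78.93
Fb	-3)-b-D-Fucp	4	3.92	68.1
Fb	-3)-b-D-Fucp	5	3.72	70.67
Fb	-3)-b-D-Fucp	6	1.203	15.583
G	a-D-Fucp(4SO3-)-(1-	1	4.974	101.6
G	a-D-Fucp(4SO3-)-(1-	2	3.824	69.05
G	a-D-Fucp(4SO3-)-(1-	3	4.103	68.03
G	a-D-Fucp(4SO3-)-(1-	4	4.584	80.95
G	a-D-Fucp(4SO3-)-(1-	5	4.37	67.172
G	a-D-Fucp(4SO3-)-(1-	6	1.254	16.14
H	a-D-Fucp(4SO3-)-(1-	1	4.918	101.34
H	a-D-Fucp(4SO3-)-(1-	2	3.831	69.38
H	a-D-Fucp(4SO3-)-(1-	3	4.074	68.37
H	a-D-Fucp(4SO3-)-(1-	4	4.546	80.55
H	a-D-Fucp(4SO3-)-(1-	5	4.338	67.33
H	a-D-Fucp(4SO3-)-(1-	6	1.307	16.38
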