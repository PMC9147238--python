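label	descriptor	position	h1	c13
I	a-L-Fucp(3Ac,4SO3-)-(1-	1	5.282	100.3
I	a-L-Fucp(3Ac,4SO3-)-(1-	2	3.785	69.0
I	a-L-Fucp(3Ac,4SO3-)-(1-	3	4.099	68.6
I	a-L-Fucp(3Ac,4SO3-)-(1-	4	4.589	81.1
I	a-L-Fucp(3Ac,4SO3-)-(1-	5	4.510	66.5
I	a-L-Fucp(3Ac,4SO3-)-(1-	6	1.258	15.8
J	-3)-b-D-Galp(2Ac,4SO3-)-(1-	1	4.773	102.8
J	-3)-b-D-Galp(2Ac,4SO3-)-(1-	2	3.731	71.6
J	-3)-b-D-Galp(2Ac,4SO3-)-(1-	3	3.908	76.5
J	-3)-b-D-Galp(2Ac,4SO3-)-(1-	4	4.692	77.3
J	-3)-b-D-Galp(2Ac,4SO3-)-(1-	5	3.798	74.4
J	-3)-b-D-Galp(2Ac,4SO3-)-(1-	6	3.802	61.0
K	-4,6)-b-D-Galp(3SO3-)-(1-	1	4.580	103.1
K	-4,6)-b-D-Galp(3SO3-)-(1-	2	3.815	68.9
K	-4,6)-b-D-Galp(3SO3-)-(1-	3	4.426	79.9
K	-4,6)-b-D-Galp(3SO3-)-(1-	4	4.540	73.8
K	-4,6)-b-D-Galp(3SO3-)-(1-	5	3.930	73.2
K	-4,6)-b-D-Galp(3SO3-)-(1-	6	4.188/3.924	70.3
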