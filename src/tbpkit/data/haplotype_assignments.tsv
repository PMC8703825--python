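species	clone_id	origin	haplotype	snps
L. minor	5500	Ireland	M1	0
L. minor	9961	Germany	M1	0
L. minor	9424	Germany	M1	0
L. minor	7194	Uganda	M2	12
L. minor	7753	Ethiopia	M2	12
L. minor	7210	S. Africa	M2	12
L. minor	9495	Norway	M3	1
L. minor	LM0011	Russia	M3	1
L. minor	7766	New Zealand	M3	1
L. minor	9536	Germany	M4	2
L. minor	7022	Spain	M4	2
L. minor	9482	Italy	M4	2
L. minor	9942	Norway	M4	2
L. minor	9533	Macedonia	M4	2
L. minor	8744	Albania	M4	2
L. minor	LM0010	Italy	M4	2
L. minor	LM0008	Russia	M4	2
L. minor	9252	Finland	M4	2
L. minor	8292	Iran	M4	2
L. gibba	7742a	Italy	G1	0
L. gibba	9598	Italy	G1	0
L. gibba	6745	California-USA	G3	6
L. gibba	8124	Arizona-USA	G3	6
L. gibba	7705	India	G2	2
L. gibba	190	USA	G2	2
L. gibba	7796	Italy	G2	2
L. gibba	9583	Poland	n.d
L. gibba	7922	Argentina	n.d
L. gibba	9614	Poland	n.d
L. gibba	9619	Albany	n.d
L. gibba	7245	S. Africa	n.d
L. gibba	8428	Switzerland	n.d
L. gibba × L. minor	7320	Egypt	G2 M4
L. gibba × L. minor	6861	Italy	G2 M4
L. gibba × L. minor	9562	Italy	G2 M4
L. gibba × L. minor	9425a	Germany	G2 M4
L. gibba × L. minor	7641	Israel	G2 M4
L. gibba × L. minor	9248	Italy	G2 M1
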