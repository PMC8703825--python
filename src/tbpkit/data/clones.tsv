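clone_id	collection	region_of_origin	country	morph_label	tbp_label
0050	Landolt Collection	Asia	China	L. japonica	L. ×japonica
0078	Landolt Collection	Asia	China	L. japonica	L. ×japonica
0150	Landolt Collection	Asia	China	L. japonica	L. ×japonica
0190	Landolt Collection	North America	USA	L. japonica	L. gibba
0198	Landolt Collection	Asia	China	L. japonica	L. ×japonica
6580	Landolt Collection	North America	USA	L. minor	L. ×japonica
6591	Landolt Collection	North America	USA	L. minor	L. minor
6619	Jena University	North America	USA	L. turionifera	L. turionifera
6728	Jena University	North America	USA	L. turionifera	L. ×japonica
6742	Landolt Collection	North America	USA	L. japonica	L. ×japonica
6745	Landolt Collection	North America	USA	L. gibba	L. gibba
6853	Jena University	North America	Canada	L. turionifera	L. turionifera
6861	Landolt Collection	Europe	Italy	L. gibba	L. gibba × L. Minor
7018	Landolt Collection	Asia	Turkey	L. minor	L. minor
7021	Landolt Collection	Europe	Spain	L. gibba	L. ×japonica
7123	Landolt Collection	North America	Canada	L. minor	L. ×japonica
7182	Landolt Collection	East Asia	Japan	L. japonica	L. ×japonica
7295	Landolt Collection	Africa	Libya	L. minor	L. minor
7320	Landolt Collection	Africa	Egypt	L. gibba	L. gibba × L. Minor
7427	Landolt Collection	East Asia	Japan	L. turionifera	L. turionifera
7432	Landolt Collection	East Asia	Japan	L. japonica	L. turionifera
7537	Landolt Collection	Europe	Spain	L. gibba	L. ×japonica
7641	Landolt Collection	Asia	Israel	L. gibba	L. gibba × L. Minor
7683	Landolt Collection	Asia	South Korea	L. turionifera	L. turionifera
7705	Landolt Collection	India	India	L. gibba	L. gibba
7767	Landolt Collection	Oceania	Australia	L. disperma	L. disperma
7777	Landolt Collection	Oceania	Australia	L. disperma	L. disperma
7798	Landolt Collection	South America	Peru	L. gibba	L. gibba
7816	Landolt Collection	Oceania	Australia	L. disperma	L. disperma
7856	Landolt Collection	North America	USA	L. obscura	L. obscura
7868	Jena University	Europe	Ireland	L. japonica	L. ×japonica
7922	Landolt Collection	South America	Argentina	L. gibba	L. gibba
7951	Landolt Collection	Asia	China	L. turionifera	L. turionifera
8227	Landolt Collection	North America	USA	L. obscura	L. obscura
8428	Landolt Collection	Europe	Switzerland	L. gibba	L. gibba
8434	Landolt Collection	North America	Canada	L. minor	L. ×japonica
8653	Landolt Collection	Asia	China	L. japonica	L. ×japonica
8697	Landolt Collection	East Asia	Japan	L. japonica	L. ×japonica
8717	Landolt Collection	Oceania	Australia	L. L. disperma	L. disperma
8760	Landolt Collection	Europe	Czech Republic	L. turionifera	L. turionifera
8892	Landolt Collection	North America	USA	L. obscura	L. obscura
9016	Landolt Collection	East Asia	Japan	L. japonica	L. ×japonica
9109	Jena University	Europe	Poland	L. turionifera	L. turionifera
9223	Landolt Collection	Europe	United Kingdom	L. minor	L. minor
9240	Landolt Collection	Europe, Asia	Russia	L. minor	L. minor
9248	Landolt Collection	Europe	Italy	L. gibba	L. gibba × L. Minor
9250	Landolt Collection	Europe	Finland	L. japonica	L. ×japonica
9253	Landolt Collection	Europe	Finland	L. minor	L. minor
9254	Landolt Collection	Europe	Finland	L. turionifera	L. turionifera
9285	Landolt Collection	Asia	China	L. japonica	L. ×japonica
9330	Landolt Collection	Asia	China	L. japonica	L. ×japonica
9345	Landolt Collection	Europe	Switzerland	L. minor	L. minor
9352	Landolt Collection	Europe	Albania	L. gibba	L. gibba
9421	Landolt Collection	North America	USA	L. japonica	L. ×japonica
9424	Landolt Collection	Europe	Germany	L. minor	L. minor
9429	Jena University	Europe, Asia	Russia	L. turionifera	L. ×japonica
9435	Landolt Collection	Europe	Albania	L. gibba	L. gibba
9438	Landolt Collection	Europe	Czech Republic	L. minor	L. minor
9439	Landolt Collection	Europe	Germany	L. minor	L. ×japonica
9470	Landolt Collection	Europe	United Kingdom	L. turionifera	L. turionifera
9471	Jena University	Europe	United Kingdom	L. turionifera	L. turionifera
9478	Jena University	Europe	Poland	L. turionifera	L. turionifera
9480	Landolt Collection	Europe, Asia	Russia	L. turionifera	L. turionifera
9482	Landolt Collection	Europe	Italy	L. minor	L. minor
9483	Landolt Collection	Europe	Albania	L. minor	L. ×japonica
9485	Landolt Collection	Europe	Ireland	L. minor	L. minor
9532	Landolt Collection	Europe	Macedonia	L. minor	L. ×japonica
9534	Landolt Collection	Europe	Germany	L. minor	L. minor
9542	Landolt Collection	Europe	Italy	L. minor	L. ×japonica
9561	Landolt Collection	Europe	Sweden	L. minor	L. minor
9562	Jena University	Europe	Germany	L. gibba	L. gibba × L. Minor
9574	Landolt Collection	Oceania	New Zealand	L. minor	L. minor
9577	Landolt Collection	Europe	Italy	L. gibba	L. gibba
9591	Landolt Collection	Europe	Hungary	L. gibba	L. ×japonica
9598	Landolt Collection	Europe	Germany	L. gibba	L. gibba
9660	Landolt Collection	Asia	China	L. japonica	L. ×japonica
9942	Landolt Collection	Europe	Norway	L. minor	L. minor
9951	Landolt Collection	Europe	France	L. gibba	L. ×japonica
9952	Landolt Collection	Europe	France	L. minor	L. minor
9961	Landolt Collection	Europe	Germany	L. minor	L. minor
9965	Landolt Collection	Europe	Switzerland	L. gibba	L. ×japonica
9967	Landolt Collection	Europe	Switzerland	L. minor	L. minor
9969	Landolt Collection	Europe	Switzerland	L. minor	L. ×japonica
9973	Landolt Collection	Europe	Germany	L. minor	L. minor
9977	Landolt Collection	Europe	Germany	L. minor	L. minor
9978	Landolt Collection	Europe	Switzerland	L. minor	L. ×japonica
9979	Landolt Collection	Europe	Germany	L. minor	L. minor
9980	Landolt Collection	Europe	Germany	L. minor	L. ×japonica
9982	Landolt Collection	North America	USA	L. japonica	L. ×japonica
9983	Landolt Collection	Europe	Switzerland	L. japonica	L. ×japonica
9986	Landolt Collection	North America	USA	L. minor	L. ×japonica
9991	Landolt Collection	North America	USA	L. japonica	L. ×japonica
8784b	Landolt Collection	Europe	Sweden	L. japonica	L. ×japonica
9425a	Landolt Collection	Europe	Italy	L. gibba	L. gibba × L. Minor
BOG0024	Greifswald University	Europe	Germany	L. turionifera	L. turionifera
BOG0071	Greifswald University	Europe	Germany	L. turionifera	L. turionifera
BOG0072	Greifswald University	Europe	Germany	L. turionifera	L. turionifera
KJA007	Jena University	Europe, Asia	Russia	L. turionifera	L. turionifera
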