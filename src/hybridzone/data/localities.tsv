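code	name	region	n
1	Sandanski	Bulgaria	4
2	Marikostinovo	Bulgaria	4
3	Plovdiv	Bulgaria	4
4	Banya	Bulgaria	4
5	Javrovo	Bulgaria	4
6	Asenovgrad	Bulgaria	3
7	Zvezdel	Bulgaria	4
8	Haskovo	Bulgaria	8
9	Thessaloniki	Greece	6
10	Thasos	Greece	6
11	Samothraki	Greece	5
12	Edirne	European Turkey	2
13	Gelibolu	European Turkey	2
14	Korudağı	European Turkey	2
15	Gölcük	European Turkey	2
16	Tekirdağ	European Turkey	9
17	İstanbul	European Turkey	12
18	İzmit	Northern Turkey	6
19	Bolu	Northern Turkey	2
20	Kastamonu	Northern Turkey	4
21	Mudanya	Southern Marmara	6
22	Karacabey	Southern Marmara	10
23	Biga	Southern Marmara	10
24	Çanakkale	Southern Marmara	10
25	Ezine	Southern Marmara	10
26	Burhaniye	Aegean Turkey	10
27	Lesvos	Greece	6
28	Chios	Greece	6
29	Samos	Greece	5
30	İzmir	Aegean Turkey	18
31	Muğla	Aegean Turkey	1
32	Rhodes	Greece	5
33	Burdur	Southern Turkey	5
34	Antalya	Southern Turkey	5
35	Anamur	Southern Turkey	2
36	Silifke	Southern Turkey	3
37	Tarsus	Southeastern Turkey	3
38	İskenderun	Southeastern Turkey	2
39	Kilis	Southeastern Turkey	2
40	Hatay	Southeastern Turkey	2
41	Kyrineia	Cyprus	4
42	Beirut	Lebanon	5
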