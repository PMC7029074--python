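locality_no	locality	COI	Pho	ITS1	STR	NH	INT
15	Gölcük	p	p	w,p	p (0.072)	p	p (0.044)
16	Tekirdağ	p	p	w	p (0.118)	p	p (0.077)
23	Biga	p	w,p	p	p (0.057)	p	p (0.012)
23	Biga	p	p	p	p (0.145)	Bkc_Pit	p (0.109)
23	Biga	p	p	p	p (0.176)	Bkc_Pit	p (0.141)
23	Biga	p	p	w,p	p (0.063)	p	p (0.047)
25	Ezine	p	w,p	p	p (0.092)	p	p (0.000)
26	Burhaniye	p	w,p	p	0.422	F2	0.413
26	Burhaniye	p	p	p	0.395	F2	0.385
26	Burhaniye	p	w,p	p	0.416	F2	0.452
26	Burhaniye	p	p	p	p (0.204)	Bkc_Pit	p (0.146)
26	Burhaniye	p	p	w,p	0.298	Bkc_Pit	0.276
26	Burhaniye	p	w,p	p	p (0.200)	Bkc_Pit	p (0.179)
26	Burhaniye	p	p	p	p (0.138)	Bkc_Pit	p (0.103)
26	Burhaniye	p	w,p	p	0.455	F2	0.443
26	Burhaniye	p	p	p	0.466	F2	0.450
26	Burhaniye	p	p	p	0.342	F2	0.326
27	Lesvos	p	p	p	0.209	Bkc_Pit	p (0.069)
27	Lesvos	p	w,p	p	p (0.042)	p	p (0.176)
27	Lesvos	p	p	p	p (0.195)	Bkc_Pit	0.198
28	Chios	p	w,p	p	p (0.052)	p	p (0.000)
30	İzmir	p	w	w	w (0.956)	w	w (1.00)
30	İzmir	p	w	—	—	—	—
30	İzmir	p	w	w	0.736	Bkc_Wil	0.757
30	İzmir	w	w	w	0.806	Bkc_Wil	0.834
30	İzmir	p	w	w	w (0.960)	w	w (1.00)
30	İzmir	p	w	w	w (0.924)	w	w (0.954)
30	İzmir	p	w	w	w (0.925)	w	w (0.957)
30	İzmir	p	w	w	w (0.859)	w	w (0.890)
30	İzmir	p	w,p	w,p	w (0.896)	w	w (0.923)
30	İzmir	w	w	w	0.744	Bkc_Wil	0.764
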