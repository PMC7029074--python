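class	efficiency	accuracy	performance	to_P_pit	to_P_wil	to_F1	to_F2	to_Bkc_Pit	to_Bkc_Wil
sim_Pit	0.983	0.957	0.941	0.983	0	0	0	0.017	0
sim_Wil	0.998	0.983	0.981	0	0.998	0	0	0	0.002
sim_F1	0.978	0.921	0.901	0	0	0.978	0.006	0.006	0.010
sim_F2	0.767	0.898	0.689	0.001	0	0.043	0.767	0.110	0.079
sim_Bkc_Pit	0.902	0.871	0.786	0.043	0	0.012	0.043	0.902	0
sim_Bkc_Wil	0.916	0.909	0.833	0	0.018	0.028	0.038	0	0.916
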