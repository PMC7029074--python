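locality_no	f_H
15	0.50
16	0.11
23	0.40
25	0.10
26	1.00
27	0.50
28	0.17
30	0.56
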