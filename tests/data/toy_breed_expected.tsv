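breed_code	Ho	He	MAF
RED	0.3888888888888889	0.3125	0.2916666666666667
BLU	0.25	0.20833333333333334	0.16666666666666666
GRN	0.5	0.3645833333333333	0.3333333333333333
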