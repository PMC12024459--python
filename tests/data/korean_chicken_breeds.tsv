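breed_name	breed_code	n_samples	fao_class	origin
Gyeongbuk Araucana	ARA	20	native	government
Rhode Island	C	20	adapted	government
Chungnam Korean Ogye	CNO	20	native	government
Chungnam white Korean native	CNW	20	native	government
Gangwon black Korean native	GWL	20	native	government
Gangwon reddish Korean native	GWR	19	native	government
Gangwon yellowish Korean native	GWY	19	native	government
Hwangbong-dak	HB	18	native	private
Hyuin black	HIL1	20	native	private
Hyuin white	HIL12	19	native	private
Hyuin yellow	HIL2	20	native	private
Hyuin grey	HIL5	20	native	private
Hoeungseong-yakdak	HYD	20	native	private
Long-tail chicken	LTC	20	native	private
Cornish	S	20	adapted	government
White Leghorn	SUL	20	adapted	university
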