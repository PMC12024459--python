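breed_code	Ho	He	MAF	FHOM	fii	si
ARA	0.2421	0.2262	0.1685	0.3071	-0.0611	-0.0231
C	0.2231	0.2181	0.1640	0.2670	-0.0217	-0.0077
CNO	0.2834	0.2723	0.2049	0.2072	-0.0402	-0.0140
CNW	0.3293	0.3078	0.2334	0.1270	-0.0646	-0.0247
GWL	0.3056	0.2904	0.2184	0.1936	-0.0398	-0.0177
GWR	0.3155	0.2970	0.2247	0.1677	-0.0590	-0.0219
GWY	0.3013	0.2794	0.2117	0.1925	-0.0730	-0.0276
HB	0.1387	0.1353	0.1012	0.5872	-0.0245	-0.0084
HIL1	0.2867	0.2668	0.2010	0.2145	-0.0700	-0.0254
HIL12	0.3167	0.3033	0.2288	0.1683	-0.0396	-0.0153
HIL2	0.2982	0.2808	0.2116	0.1975	-0.0584	-0.0213
HIL5	0.3005	0.2796	0.2102	0.1909	-0.0706	-0.0258
HYD	0.0440	0.0388	0.0306	0.8524	-0.1264	-0.0526
LTC	0.2575	0.2665	0.2002	0.2910	0.0230	0.0115
S	0.2842	0.2755	0.2078	0.2125	-0.0304	-0.0109
SUL	0.2551	0.2420	0.1813	0.1223	-0.0489	-0.0182
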