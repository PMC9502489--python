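subject_id	group	age	sex	off_therapy_years	IQ	TMT_A	DST
A01	A	13.662598959868305	0		102.88631973393898	51.947403163389339	8.0453843781421259
A02	A	8.8581410116339239	0		98.631474566911848	-4.5269308022882768	7.5513388917340247
A03	A	7.8065567813387746	0		99.975466256447348	27.65159033246935	6.0232719318715446
B01	B	8.7769071966890522	0	5.0039149350172476	103.98525431133433	12.772993959679088	7.1578458425678262
B02	B	13.232114231204656	1	2.765628258530032	102.65010543449736	45.555005865321519	6.329025369438197
B03	B	9.5318505592179132	0	3.8046771112373188	100.11356141866924	24.200956278362035	7.11066606555727
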