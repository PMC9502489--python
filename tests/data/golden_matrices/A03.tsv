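	1	2	3	4	5	6	7	8
1	0	0.82601525454043478	0.63368305905033451	0.93720073282947214	0.44682729537164484	0.74182944137345352	0.45149106953735041	0.82602095333990078
2	0.82601525454043478	0	0.82188655060940852	0.75973229763169881	0.8433607294163602	0.87985385798101989	0.65802691719716	0.78050652571212575
3	0.63368305905033451	0.82188655060940852	0	0.77886189622290114	0.80653741374563659	0.82856903222229084	0.4133411975481911	0.67684232346332951
4	0.93720073282947214	0.75973229763169881	0.77886189622290114	0	0.45243912283284687	0.81841800078993554	0.36787944117144233	0.84759393217434853
5	0.44682729537164484	0.8433607294163602	0.80653741374563659	0.45243912283284687	0	0.77510746681569753	0.68501351473993477	0.57205988971463007
6	0.74182944137345352	0.87985385798101989	0.82856903222229084	0.81841800078993554	0.77510746681569753	0	0.74221157226637136	1
7	0.45149106953735041	0.65802691719716	0.4133411975481911	0.36787944117144233	0.68501351473993477	0.74221157226637136	0	0.68672301539740666
8	0.82602095333990078	0.78050652571212575	0.67684232346332951	0.84759393217434853	0.57205988971463007	1	0.68672301539740666	0
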