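	1	2	3	4	5	6	7	8
1	0	0.79739389188856102	0.84289221433524353	0.89690178136282261	0.71054125996066275	0.68388707457534559	1	0.86407194293172207
2	0.79739389188856102	0	0.46648957304434668	0.65291672632583353	0.42190036507498907	0.90536462366878279	0.88716478457978498	0.55233312257596101
3	0.84289221433524353	0.46648957304434668	0	0.75081248307387838	0.80801668363251677	0.36787944117144233	0.76852943706323662	0.87525772464796758
4	0.89690178136282261	0.65291672632583353	0.75081248307387838	0	0.82545367989205032	0.67045445172154072	0.91566571855937096	0.97515201092800685
5	0.71054125996066275	0.42190036507498907	0.80801668363251677	0.82545367989205032	0	0.45051402195523188	0.74003413626816283	0.98443445587129608
6	0.68388707457534559	0.90536462366878279	0.36787944117144233	0.67045445172154072	0.45051402195523188	0	0.84649246866580052	0.56153334544257549
7	1	0.88716478457978498	0.76852943706323662	0.91566571855937096	0.74003413626816283	0.84649246866580052	0	0.82845522521263026
8	0.86407194293172207	0.55233312257596101	0.87525772464796758	0.97515201092800685	0.98443445587129608	0.56153334544257549	0.82845522521263026	0
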