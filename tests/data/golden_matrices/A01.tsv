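	1	2	3	4	5	6	7	8
1	0	0.85207006649663508	0.99118443537072298	0.89879789816263334	0.67334441679465329	0.99845557810103325	0.96348956199538105	0.89114851403378259
2	0.85207006649663508	0	0.8898811195022438	0.54462932081275939	0.97040656602643027	0.76987352322323765	0.6672872241636546	0.58570927738190881
3	0.99118443537072298	0.8898811195022438	0	0.83200709354885938	0.77146007983754317	0.92016468028464116	0.87803835441428246	0.87428854731792083
4	0.89879789816263334	0.54462932081275939	0.83200709354885938	0	0.36787944117144233	0.93679546122402468	0.97858848838502666	1
5	0.67334441679465329	0.97040656602643027	0.77146007983754317	0.36787944117144233	0	0.57210058313654566	0.46878960064139635	0.42359575741015842
6	0.99845557810103325	0.76987352322323765	0.92016468028464116	0.93679546122402468	0.57210058313654566	0	0.9847129803704443	0.92622043086364103
7	0.96348956199538105	0.6672872241636546	0.87803835441428246	0.97858848838502666	0.46878960064139635	0.9847129803704443	0	0.93782575278171576
8	0.89114851403378259	0.58570927738190881	0.87428854731792083	1	0.42359575741015842	0.92622043086364103	0.93782575278171576	0
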