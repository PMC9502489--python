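	1	2	3	4	5	6	7	8
1	0	0.96583432820350845	0.6847514236452017	0.52454702061953717	0.89735711697277953	0.67336630791496832	0.91749361420228293	0.97443666059487977
2	0.96583432820350845	0	0.69130387266309001	0.48363404878501914	0.90425251899983738	0.83268631754757738	0.82765217603866792	0.92946373309063257
3	0.6847514236452017	0.69130387266309001	0	0.36787944117144233	0.59071860836638479	0.72113989777522425	0.85163480860091256	0.80923405138875393
4	0.52454702061953717	0.48363404878501914	0.36787944117144233	0	0.67436199706040723	0.41812522871079255	0.60710594637170634	0.61679186210823078
5	0.89735711697277953	0.90425251899983738	0.59071860836638479	0.67436199706040723	0	0.62966886032295188	0.75758810210660454	1
6	0.67336630791496832	0.83268631754757738	0.72113989777522425	0.41812522871079255	0.62966886032295188	0	0.77152967577410814	0.75867164598811576
7	0.91749361420228293	0.82765217603866792	0.85163480860091256	0.60710594637170634	0.75758810210660454	0.77152967577410814	0	0.92433555020391311
8	0.97443666059487977	0.92946373309063257	0.80923405138875393	0.61679186210823078	1	0.75867164598811576	0.92433555020391311	0
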