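	1	2	3	4	5	6	7	8
1	0	0.97816604719860378	0.9586388895296879	0.76979498720296546	0.9880752047951743	0.78315474669513319	0.68226683471822158	0.92709788823214201
2	0.97816604719860378	0	1	0.81487756675722756	0.98181638165560681	0.76693826723854641	0.62822843983779453	0.98755885067041593
3	0.9586388895296879	1	0	0.8107744051167346	0.97817393807450281	0.81836108088840431	0.6888859286703154	0.97638311243587428
4	0.76979498720296546	0.81487756675722756	0.8107744051167346	0	0.71014452709428177	0.56328911447759678	0.36787944117144233	0.82494274037714788
5	0.9880752047951743	0.98181638165560681	0.97817393807450281	0.71014452709428177	0	0.89278610975193684	0.79488387264342397	0.9796403094816355
6	0.78315474669513319	0.76693826723854641	0.81836108088840431	0.56328911447759678	0.89278610975193684	0	0.98679634600850819	0.89797867618914107
7	0.68226683471822158	0.62822843983779453	0.6888859286703154	0.36787944117144233	0.79488387264342397	0.98679634600850819	0	0.75573044478641216
8	0.92709788823214201	0.98755885067041593	0.97638311243587428	0.82494274037714788	0.9796403094816355	0.89797867618914107	0.75573044478641216	0
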