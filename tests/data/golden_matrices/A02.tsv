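	1	2	3	4	5	6	7	8
1	0	0.60225245299243946	0.82523458560055429	0.79333553060310402	0.57788513107196238	0.60624291340903447	0.95077660764508043	0.94678025947697642
2	0.60225245299243946	0	0.44826522311456118	0.83827176728529473	0.93894850003590002	1	0.69737641926488458	0.72892431543613012
3	0.82523458560055429	0.44826522311456118	0	0.47765234025436537	0.36787944117144233	0.4872501401892268	0.74332756646060882	0.86694750984713109
4	0.79333553060310402	0.83827176728529473	0.47765234025436537	0	0.87644892204018943	0.80550096576649532	0.88075358233024936	0.78529838900493454
5	0.57788513107196238	0.93894850003590002	0.36787944117144233	0.87644892204018943	0	0.87302796259873472	0.68918231788671591	0.62374148683598851
6	0.60624291340903447	1	0.4872501401892268	0.80550096576649532	0.87302796259873472	0	0.67250647342660186	0.74806529097719487
7	0.95077660764508043	0.69737641926488458	0.74332756646060882	0.88075358233024936	0.68918231788671591	0.67250647342660186	0	0.94542278149731274
8	0.94678025947697642	0.72892431543613012	0.86694750984713109	0.78529838900493454	0.62374148683598851	0.74806529097719487	0.94542278149731274	0
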