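Expert,Party,Decentralization,Environment,EU Accountability,EU Authority,EU Peacekeeping,Immigration,Social,Taxes vs Spending,Ideological Scaling
1,DKP,15,10,6,17,16,10,8,3,4
1,PDS,10,3,6,10,16,10,8,3,3
1,GR,3,6,3,11,5,3,2,14,6
1,SPD,7,11,12,11,8,9,8,7,9
1,FDP,3,14,5,9,5,3,2,17,11
1,CDU,7,15,13,9,7,9,16,11,12
1,Sch,10,13,15,15,12,16,15,13,15
1,Rep,14,13,16,17,17,18,17,10,18
1,DVU,14,13,16,17,17,18,10,10,19
1,NPD,14,13,16,17,17,18,10,10,18
2,DKP,5,8,1,12,6,8,4,2,3
2,PDS,7,10,1,14,8,4,1,1,5
2,GR,5,4,1,8,6,7,5,11,8
2,SPD,8,9,9,11,8,10,7,10,10
2,FDP,8,14,9,10,6,11,6,20,13
2,CDU,8,15,11,13,8,18,18,19,14
2,Sch,6,19,5,20,20,20,18,8,18
2,Rep,6,18,5,20,20,20,19,9,19
2,DVU,6,17,5,20,20,20,20,9,19
2,NPD,6,19,5,20,20,20,20,8,20
3,DKP,8,3,2,8,19,4,2,3,1
3,PDS,8,3,2,6,18,2,2,3,3
3,GR,6,5,6,9,6,6,3,10,8
3,SPD,14,9,7,9,5,7,10,7,6
3,FDP,9,17,8,10,5,8,6,19,16
3,CDU,13,15,13,10,5,16,15,13,14
3,Sch,4,11,14,12,4,20,20,16,20
3,Rep,4,11,14,12,4,20,20,16,20
3,DVU,4,11,14,12,4,20,20,16,19
3,NPD,4,11,14,12,4,20,20,16,20
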