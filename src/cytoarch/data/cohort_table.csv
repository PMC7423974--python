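patient_id,age,sex,subtype,autoantibody,disease_duration,medication,organ_involvement,skin_score,fvc_pct,dlco_pct
1,59,F,LcSSc,ACA,11.70,No,V;GI,10,92,65
2,48,M,LcSSc,Topo-I,3.13,P;MMF,V;GI;ILD,0,54,31
3,50,F,LcSSc,Topo-I,5.21,CYC,M;V;GI;ILD,3,47,44
4,42,F,LcSSc,No,1.37,No,M;V;GI,0,68,82
5,42,F,LcSSc,ACA,1.52,P,M;V;GI,5,91,76
6,35,M,LcSSc,Topo-I,0.44,P,Cardiac;M;V;GI;ILD,6,60,49
7,60,F,DcSSc,Topo-I,1.16,No,M;V;GI;ILD,10,53,64
8,61,F,DcSSc,No,0.68,No,V;GI;ILD,27,52,25
9,24,F,DcSSc,No,3.26,No,Cardiac;M;V;GI,2,76,129
10,45,F,DcSSc,No,0.27,No,GI,8,100,98
11,52,F,DcSSc,No,3.45,MTX,M;V;GI,2,79,68
12,31,F,LcSSc,Topo-I,0.96,P;MMF,M;GI;ILD,6,48,35
13,63,F,LcSSc,Topo-I,6.84,No,M;V;GI,1,81,81
14,39,F,DcSSc,Topo-I,11.79,CYC,M;V;GI,17,96,86
15,42,F,DcSSc,Topo-I,2.24,P;CYC,Cardiac;M;V;GI;ILD,12,58,53
16,60,F,DcSSc,Topo-I,9.56,MMF,M;V;ILD,28,68,48
17,22,F,DcSSc,Topo-I,1.00,No,M;V;GI;ILD,45,43,48
18,47,F,DcSSc,No,3.91,P;MMF,M;V;GI;ILD,0,79,52
19,62,F,LcSSc,No,10.93,No,M;V;GI;ILD,3,89,68
20,55,F,LcSSc,No,26.53,No,M;V;GI,8,93,70
21,33,F,LcSSc,ACA,2.43,P;MMF,M;V;GI,0,96,101
22,59,F,LcSSc,Topo-I,10.45,MTX,M;V;GI;ILD,0,74,65
23,36,F,DcSSc,Topo-I,0.27,MMF,M;GI,25,,
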