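patient_id,gender,age,histology,who_grade,side,local_anatomy,margins,volume_cm3,bg_voxels,onset,procedure,n_mri
1,M,61,A,2,R,P,B,24.4,4,INCIDENTAL/TINNITUS,R,2
2,M,66,A,2,L,F,B,31.1,7,SEIZURE PAR-COMPLEX,B,3
3,F,65,A,3,B,F,D,108,16,SEIZURES PAR,B,4
4,F,30,O,2,R,F,B,5.1,1,HEADACHE,R,4
5,M,38,A,2,L,F,B,33,2,SEIZURES PAR,R,4
6,F,27,A,3,R,F,B,54.6,8,SEIZURE PAR,R,2
7,M,31,O,3,R,T,D,98.2,13,SEIZURE GEN,R,2
8,F,31,A,3,L,F-P,B,38.5,5,SEIZURE PAR,B,9
9,F,31,O,2,R,F,D,114.3,12,SEIZURE GEN,R,2
10,F,42,O,2,R,F,B,71.7,8,SEIZURE GEN,R,2
11,M,25,O,2,L,P,D,30.9,7,NUMBNESS R LEG,R,2
12,F,78,A,3,L,F,D,10.4,1,SEIZURE GEN,R,2
13,F,62,A,2,R,T-I,D,58.5,10,SEIZURE PAR,B,6
14,F,22,A,2,R,F-P,B,61.6,9,SEIZURE PAR,R,2
15,M,70,A,3,R,T,D,85.7,13,SEIZURE PAR,B,2
16,F,40,O,3,R,F-P,D,36.1,7,SEIZURE PAR,R,2
17,M,52,A,2,R,P-O,D,19.2,7,SEIZURE GEN,R,2
18,M,41,A,2,L,T,D,26.7,7,SEIZURE GEN,R,2
19,F,44,A,2,L,FTI,D,30.4,8,SEIZURE GEN,R,2
20,M,67,A,2,L,T-P,D,141.7,14,SEIZURE GEN,B,4
21,F,43,O,2,R,F,D,78.5,11,SEIZURE GEN,R,2
22,F,66,A,2,L,T,D,64.5,10,SEIZURE PAR,R,2
23,M,44,O,2,R,F,B,22.9,2,SEIZURE GEN,R,2
24,M,60,A,2,R,F,B,20.1,6,WEAKNESS L HEMIBODY,R,2
25,M,54,O,2,L,T,B,33.9,4,SEIZURE PAR,R,2
26,M,44,O,2,R,F,B,37.2,4,SEIZURE GEN,R,2
27,F,40,O,2,L,F,D,17.2,6,HEADACHE/DYZZINESS,R,4
28,F,68,O,3,L,F,B,6.5,1,SEIZURE PAR,R,2
29,M,34,O,2,L,F-I,D,35.1,6,HEADACHE,B,7
30,M,26,O,2,R,F,B,36.7,6,SEIZURE GEN,R,2
31,M,39,O,2,L,F,D,62.1,6,HEADACHE,R,2
32,F,50,A,3,L,T,D,129.8,12,SEIZURE GEN,R,2
33,M,54,O,3,L,F-T-I,D,93.3,13,SEIZURE PAR-COMPLEX,R,2
34,F,61,A,3,R,F,D,34.3,7,SEIZURE GEN,R,2
35,M,53,O,3,L,F,D,91.1,12,SEIZURE GEN,R,2
36,M,26,O,3,L,F,D,34.1,3,INCIDENTAL,R,2
37,F,45,O,3,L,F,B,24.6,5,ICH/VISION IMPAIRMENT,R,2
38,M,47,O,3,R,F,D,65.5,8,SEIZURE GEN,R,2
39,M,33,A,2,L,F,B,50.6,5,SEIZURE GEN,R,2
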