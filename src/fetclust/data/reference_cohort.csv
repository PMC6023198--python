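id,histology,mib1,idh1,who_grade,pct_c1,pct_c2,pct_c3,suv_max,suv_mean,tbr_max,tbr_mean,ttp_min,slope_suv_per_h
1,Oligodendroglioma,5,+,II,98.2,0.1,1.7,3.6,2.1,4.1,2.4,45,1.23
2,Anaplastic astrocytoma,20,-,III,5.2,54.6,40.2,2.4,1.5,4.0,2.5,15,-0.72
3,Anaplastic astrocytoma,5,-,III,27.3,70.8,1.9,2.2,1.8,2.4,2.0,25,-0.43
4,Oligodendroglioma,15,+,II,7.5,57.4,35.1,3.4,2.1,3.8,2.3,15,-0.28
5,Low-grade glioma,0,+,I,97.2,0,2.8,1.4,1.1,1.6,1.2,30,0.14
6,Anaplastic oligoastrocytoma,,+,III,95.3,4.7,0,4.0,2.2,3.1,1.7,45,0.05
7,Secondary glioblastoma,15,+,IV,100,0,0,1.1,1.0,1.2,1.1,45,0.35
8,Anaplastic oligoastrocytoma,10,+,III,5.2,33.9,60.9,1.7,1.2,2.4,1.7,10,-0.32
9,Primary glioblastoma,30,-,IV,99.9,0,0.1,3.7,2.1,4.4,2.6,45,0.79
10,Anaplastic oligodendroglioma,60,-,III,54.3,45.7,0,2.3,1.6,3.3,2.3,35,-0.26
11,Oligoastrocytoma,15,+,II,71.7,28.3,0,2.2,1.7,2.8,2.1,40,0.11
12,Oligoastrocytoma,15,-,II,10.9,24.8,64.3,2.9,2.1,3.3,2.5,10,-0.83
13,Primary glioblastoma,40,-,IV,27.6,31.3,41.1,2.4,1.6,3.0,2.0,10,-0.61
14,Anaplastic oligoastrocytoma,30,-,III,89.9,9.7,0.4,2.4,1.9,2.0,1.6,45,-0.07
15,Anaplastic oligodendroglioma,60,-,III,15.5,33.5,51,2.5,1.8,3.2,2.1,10,-0.65
16,Oligoastrocytoma,10,-,II,11.8,28.8,59.4,3.3,2.0,4.1,2.5,10,-0.96
17,Oligodendroglioma,10,+,II,14.6,83,2.4,2.6,1.4,2.9,1.6,15,-1.01
18,Anaplastic astrocytoma,10,+,III,12.6,85.7,1.7,2.2,1.7,1.8,1.4,20,0.06
19,Anaplastic astrocytoma,40,-,III,81.9,10.2,7.9,4.0,2.3,6.7,3.8,40,0.55
20,Diffuse astrocytoma,5,-,II,21.1,66.4,12.5,3.3,2.4,3.7,2.6,20,-1.16
21,Ganglioglioma,2,-,II,1.8,28.9,69.3,2.6,1.5,4.3,2.5,10,-0.70
22,Anaplastic oligoastrocytoma,2,+,III,98.6,0.1,1.3,2.2,1.7,2.4,1.9,45,1.11
23,Low-grade glioma,3,-,I,6.5,76.7,16.8,2.6,1.9,2.9,2.1,15,-0.50
24,Anaplastic astrocytoma,10,-,III,14.5,47.6,37.9,2.4,1.6,3.4,2.3,15,-0.68
25,Anaplastic oligodendroglioma,20,+,III,42.2,28.8,29,3.5,2.3,3.9,2.5,20,-0.91
26,Oligodendroglioma,3,+,II,98.8,1.1,0.1,2.7,2.0,3.4,2.5,45,0.34
27,Gemistocytic astrocytoma,0,+,II,93.5,6.5,0,2.2,1.7,2.9,2.2,35,0.32
28,Oligoastrocytoma,1,+,II,100,0,0,1.6,1.4,2.3,2.0,45,0.56
29,Oligoastrocytoma,10,+,II,97.2,2.7,0.1,3.3,2.2,3.4,2.1,45,0.34
30,Primary glioblastoma,30,-,IV,9.3,50.3,40.4,5.4,2.9,5.3,2.8,10,-0.94
31,Oligoastrocytoma,10,-,II,93.5,3.3,3.2,4.5,3.3,4.9,3.8,40,0.43
32,Diffuse astrocytoma,3,-,II,0,0.1,99.9,1.4,1.2,1.9,1.4,5,-0.66
33,SEGA,1,-,I,100,0,0,2.9,1.8,4.1,2.6,45,0.54
34,Oligodendroglioma,5,+,II,92.5,7.5,0,2.2,1.8,2.8,2.3,45,0.13
35,Anaplastic oligoastrocytoma,8,+,III,30.8,57.1,12.1,1.8,1.4,2.6,2.0,25,-0.08
36,Primary glioblastoma,80,-,IV,73.5,26.5,0,1.9,1.4,2.7,2.0,45,-0.31
37,Anaplastic astrocytoma,40,-,III,50.6,22.5,26.9,2.1,1.8,2.2,1.9,20,0.04
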