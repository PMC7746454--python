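subject_id,sequence,age,b1,y1,b2,y2
1,BA,52.91,1.5,1,1,1.5
2,AB,65,1,1,1,2.5
3,BA,45.79,6,4,3.5,>10
4,AB,40,6,>10,2.5,2.5
5,BA,64.37,1,1,1.5,4.5
6,AB,59.08,3,2,1,0.5
7,BA,54.13,3.5,1.5,0.5,3
8,AB,63.46,2.5,2.5,1.5,2
9,BA,61.14,0.5,1,3.5,8
10,AB,51.78,2,2.5,2.5,3
11,BA,47.59,6,10,6,>10
12,AB,58.59,1.5,4.5,2.5,1
13,BA,70,0.5,0.5,1,>10
14,AB,55.08,3.5,5.5,4.5,9.5
15,BA,57.28,1,1,1,2.5
16,AB,65.16,1,2,2,>10
17,BA,59.75,1.5,1,0.5,0.5
18,AB,41.34,6,>10,5,3.5
19,BA,67.77,1,1.5,2,4
20,AB,59.44,2,3,1.5,1.5
21,BA,42.91,5,5.5,3,1.5
22,AB,65.54,1.5,2.5,1.5,0.5
23,BA,50.72,2.5,5,6,4.5
24,AB,70,1.5,3.5,2.5,3
25,BA,47.01,5,5.5,4.5,6
26,AB,55.63,3.5,9,6,6
27,BA,62.26,1,2,2.5,8.5
28,AB,62.93,2,5.5,3.5,8
29,BA,40,5,5.5,3.5,2
30,AB,56.67,2.5,2.5,1,0.5
31,BA,66.27,0.5,1,2,7.5
32,AB,63.13,2.5,3.5,2.5,4
33,BA,48.16,5,4,2,2
34,AB,41.62,5.5,3,1,0.5
35,BA,65.04,0.5,0.5,1,1.5
36,AB,55.70,3,5.5,5,0.5
37,BA,66.49,1.5,2,3,3
38,AB,66.62,0.5,1,1,5.4
39,BA,43.19,6,4,1.5,0.5
40,AB,53.10,2.5,5,2.5,0.5
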