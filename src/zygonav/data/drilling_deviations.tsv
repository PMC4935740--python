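site	hole	deviation_mm
1	1	0.977
1	2	0.748
1	3	1.032
1	4	0.553
1	5	0.497
1	6	0.522
1	7	0.862
1	8	1.164
1	9	1.188
1	10	0.243
1	11	1.477
1	12	1.295
2	1	0.231
2	2	0.914
2	3	0.907
2	4	1.360
2	5	0.655
2	6	0.668
2	7	1.152
2	8	0.822
2	9	0.547
2	10	0.516
2	11	1.054
2	12	1.253
3	1	0.760
3	2	0.548
3	3	1.405
3	4	1.066
3	5	1.340
3	6	0.240
3	7	0.633
3	8	0.337
3	9	1.243
3	10	0.767
3	11	0.372
3	12	0.506
4	1	0.759
4	2	0.867
4	3	1.017
4	4	1.628
4	5	0.941
4	6	1.241
4	7	1.426
4	8	0.978
4	9	1.757
4	10	1.511
4	11	0.833
4	12	0.895
5	1	1.025
5	2	0.871
5	3	0.57
5	4	1.691
5	5	0.666
5	6	0.669
5	7	1.010
5	8	0.626
5	9	0.713
5	10	0.806
5	11	0.174
5	12	0.608
6	1	0.911
6	2	0.449
6	3	1.317
6	4	1.294
6	5	1.349
6	6	0.781
6	7	1.235
6	8	0.713
6	9	1.547
6	10	1.568
6	11	0.873
6	12	1.331
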