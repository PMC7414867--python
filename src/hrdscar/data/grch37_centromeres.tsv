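chrom	cen_start	cen_end
1	121535435	124535434
2	92326172	95326171
3	90504855	93504854
4	49660118	52660117
5	46405642	49405641
6	58830167	61830166
7	58054332	61054331
8	43838888	46838887
9	47367680	50367679
10	39254936	42254935
11	51644206	54644205
12	34856695	37856694
13	16000001	19000000
14	16000001	19000000
15	17000001	20000000
16	35335802	38335801
17	22263007	25263006
18	15460899	18460898
19	24681783	27681782
20	26369570	29369569
21	11288130	14288129
22	13000001	16000000
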