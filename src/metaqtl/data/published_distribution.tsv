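chr	stress	n_qtls	n_mqtls
1H	drought	18	4
1H	low_temperature	2	2
1H	waterlogging	11	4
1H	salinity	21	6
1H	mineral	12	4
2H	drought	54	6
2H	low_temperature	1	1
2H	waterlogging	10	4
2H	salinity	43	8
2H	mineral	12	4
3H	drought	43	6
3H	low_temperature	0	0
3H	waterlogging	8	4
3H	salinity	23	5
3H	mineral	25	2
4H	drought	32	4
4H	low_temperature	2	1
4H	waterlogging	8	3
4H	salinity	39	8
4H	mineral	15	4
5H	drought	16	4
5H	low_temperature	9	1
5H	waterlogging	3	2
5H	salinity	23	6
5H	mineral	7	2
6H	drought	21	2
6H	low_temperature	2	1
6H	waterlogging	2	2
6H	salinity	22	4
6H	mineral	12	3
7H	drought	26	6
7H	low_temperature	0	0
7H	waterlogging	5	4
7H	salinity	35	7
7H	mineral	23	4
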