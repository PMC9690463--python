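mqtl_id	chr	r2_meta	peak_bp	ci_lo_bp	ci_hi_bp
MQTL1.1	1H	0.07	120604292	113763968	128399829
MQTL1.2	1H	0.22	191424829	187288939	198521321
MQTL1.3	1H	0.22	215895490	209987507	219651209
MQTL1.4	1H	0.15	227122225	224396043	241295755
MQTL1.5	1H	0.11	274117654	257758192	281940383
MQTL1.6	1H	0.22	328366571	317252081	331517042
MQTL2.1	2H	0.09	42367561	39815442	44919679
MQTL2.2	2H	0.2	68439906	64629701	72250111
MQTL2.3	2H	0.09	97387878	91468880	103306875
MQTL2.4	2H	0.04	139419949	135909288	142930609
MQTL2.5	2H	0.22	170213114	166570654	173855574
MQTL2.6	2H	0.06	189767373	187766416	191768330
MQTL2.7	2H	0.1	263383407	256445958	270320855
MQTL2.8	2H	0.12	294464135	290701857	298226412
MQTL2.9	2H	0.07	611525900	608806036	614245763
MQTL3.1	3H	0.09	268408330	261707356	275109306
MQTL3.2	3H	0.23	379792248	376613242	384250770
MQTL3.3	3H	0.1	436460332	428189641	444731023
MQTL3.4	3H	0.17	473526748	471178768	475874727
MQTL3.5	3H	0.31	498826884	495476397	502177372
MQTL3.6	3H	0.07	573909459	563449078	584369838
MQTL4.1	4H	0.07	182695125	175965050	193845575
MQTL4.2	4H	0.08	250437750	245089075	255786425
MQTL4.3	4H	0.04	285624125	277921575	293326675
MQTL4.4	4H	0.03	317672025	304090350	331253725
MQTL4.5	4H	0.12	339354100	332668250	346039950
MQTL4.6	4H	0.17	352946825	348117550	357776125
MQTL4.7	4H	0.17	403538300	400996575	406080025
MQTL4.8	4H	0.32	462329625	460130475	465799650
MQTL5.1	5H	0.03	11389965	9196970	13582960
MQTL5.2	5H	0.12	121232310	120331310	122133305
MQTL5.3	5H	0.09	135954265	133744270	138164260
MQTL5.4	5H	0.14	152138215	149316225	154960210
MQTL5.5	5H	0.07	177842140	174833150	180851130
MQTL5.6	5H	0.06	197188085	192853095	201523070
MQTL5.7	5H	0.06	206322725	204237395	208408050
MQTL5.8	5H	0.26	239937290	238061630	241812955
MQTL5.9	5H	0.19	262479225	262054225	262904225
MQTL6.1	6H	0.12	129309961	120005985	138613926
MQTL6.2	6H	0.07	198777337	181047449	216507225
MQTL6.3	6H	0.55	256188394	251612394	260764394
MQTL6.4	6H	0.26	320961575	319965327	321957823
MQTL7.1	7H	0.15	172041612	165726420	178356810
MQTL7.2	7H	0.11	205841892	197894802	213788982
MQTL7.3	7H	0.07	224776302	218058726	231493884
MQTL7.4	7H	0.06	248606394	240290454	256922334
MQTL7.5	7H	0.11	278695794	273308316	284083272
MQTL7.6	7H	0.21	293069850	289839600	296300106
MQTL7.7	7H	0.01	311177142	306538548	319839582
MQTL7.8	7H	0.04	352488594	345402156	359575026
MQTL7.9	7H	0.08	381929706	374642082	389217330
MQTL7.10	7H	0.16	413807478	411996750	415618206
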