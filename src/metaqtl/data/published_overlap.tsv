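mqtl_id	low_temperature	mineral	waterlogging	salinity	drought
MQTL1.1	1	3	2	1	0
MQTL1.2	0	0	5	5	4
MQTL1.3	0	1	3	10	4
MQTL1.4	0	0	0	1	2
MQTL1.5	1	1	0	2	0
MQTL1.6	0	7	1	2	8
MQTL2.1	1	0	0	14	0
MQTL2.2	0	7	0	7	18
MQTL2.3	0	1	0	0	8
MQTL2.4	0	2	2	1	1
MQTL2.5	0	0	5	4	14
MQTL2.6	0	2	0	2	0
MQTL2.7	0	0	2	5	12
MQTL2.8	0	0	1	4	1
MQTL2.9	0	0	0	6	0
MQTL3.1	0	0	1	2	5
MQTL3.2	0	7	4	8	5
MQTL3.3	0	0	2	3	8
MQTL3.4	0	0	1	0	14
MQTL3.5	0	18	0	8	5
MQTL3.6	0	0	0	2	6
MQTL4.1	0	0	0	5	0
MQTL4.2	0	0	1	1	6
MQTL4.3	0	2	0	1	0
MQTL4.4	0	0	0	1	0
MQTL4.5	0	1	0	5	5
MQTL4.6	0	0	0	15	3
MQTL4.7	0	9	4	1	0
MQTL4.8	2	3	3	10	18
MQTL5.1	0	0	0	2	0
MQTL5.2	9	0	0	8	0
MQTL5.3	0	0	0	5	0
MQTL5.4	0	5	0	2	2
MQTL5.5	0	0	0	0	1
MQTL5.6	0	0	2	0	0
MQTL5.7	0	0	1	0	0
MQTL5.8	0	0	0	1	11
MQTL5.9	0	2	0	5	2
MQTL6.1	2	0	1	3	0
MQTL6.2	0	1	0	1	0
MQTL6.3	0	9	1	9	19
MQTL6.4	0	2	0	9	2
MQTL7.1	0	11	2	10	2
MQTL7.2	0	0	0	0	6
MQTL7.3	0	0	1	2	0
MQTL7.4	0	7	1	0	0
MQTL7.5	0	0	0	7	0
MQTL7.6	0	0	0	6	6
MQTL7.7	0	3	0	0	0
MQTL7.8	0	0	0	1	2
MQTL7.9	0	0	1	5	1
MQTL7.10	0	2	0	4	9
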