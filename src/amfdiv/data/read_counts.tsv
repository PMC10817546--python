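stp_id	total_reads	merged_reads	amf_reads_its1	amf_otus_its1	amf_reads_its2	amf_otus_its2
STP1	1494700	401850	1243	100	546	72
STP3	619855	255057	1011	59	493	49
STP4	1648642	626988	1116	86	580	74
STP7	652998	102472	183	29	7	3
STP8	1469158	586935	76	26	24	10
STP9	970340	539334	697	80	583	58
STP11	1108444	363547	6670	197	1624	128
STP12	1271980	160449	335	66	885	93
STP13	862545	347435	4638	109	1758	76
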