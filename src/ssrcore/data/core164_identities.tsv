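accession	identity
TJ2	D1002322100
TJ5	202023AA10B
TJ7	20A021A1100
TJ9	B0002AD2000
TJ19	DA0032D110A
TJ24	B02012B100A
TJ27	22202D3AA0B
TJ28	AD0033A200A
TJ32	DD002D22A00
TJ34	C220132B00A
TJ39	D0200B32000
TJ48	33A00D21000
TJ49	F3000221201
TJ59	3D00232A000
TJ63	C2202BA3100
TJ84	22000A23B2A
TJ89	EAA04AA221A
TJ97	21F00BB2031
TJ102	2D2002A220A
TJ105	2320022212A
TJ109	4130022A011
TJ114	EFF0032D22A
TJ116	3030032211B
TJ124	4130423E010
TJ131	A200A2D211A
TJ132	EDA002A2230
TJ137	DFD03DD202A
TJ139	BF4002D2231
TJ152	2300032211A
TJ153	2A2002AB02A
TJ160	33D0023202A
TJ166	3200122A00A
TJ173	2A00242200A
TJ174	3A00232D001
TJ179	4300213200A
TJ181	40004322001
TJ208	BB00322D00A
TJ209	FF00333200A
TJ216	2000232A00B
TJ217	DA00223200B
TJ259	4123D222221
TJ264	3AA1222321B
TJ265	EA21A12211A
TJ270	3132A23D21B
TJ284	3320131221A
TJ295	BAA213D112A
TJ296	D3A01321211
TJ308	2D10DD3121A
TJ311	D222332101B
TJ323	220A12BA000
TJ329	A20DAC2D00D
TJ342	C2AF03BF001
TJ348	2A430E3300A
TJ349	2A230B33001
TJ359	32230AA3001
TJ371	322A1A2A000
TJ374	024D0FDD00D
TJ380	A2320F3200A
TJ381	D21300B3000
TJ394	B20DDFDD00A
TJ397	C2024EA200D
TJ398	EA322EB200A
TJ413	1A2401D4102
TJ414	D233022320A
TJ421	3D2D03DD301
TJ422	21010D3110A
TJ427	D20DDBADA0B
TJ434	D3DD02BD20B
TJ446	31020D32201
TJ448	DFD20D2220A
TJ450	3A0203D2A0A
TJ453	D2B20D32201
TJ455	DD030B33201
TJ478	02D20332201
TJ480	A414023020A
TJ491	02101223A0C
TJ496	A2102A2230A
TJ498	AA30222DD0B
TJ499	A2102322D0B
TJ502	DD102222D0A
TJ509	22A02B3D30B
TJ510	A3202D22D0A
TJ512	BA3013A3A0A
TJ515	0A20223230A
TJ518	BD102BDDA01
TJ521	211023B2D0A
TJ522	AA302DB2D0A
TJ524	03202ABDA0A
TJ529	23A0222D201
TJ534	0A202B3DA01
TJ545	332021A230A
TJ546	2A102322D0A
TJ552	0220023DA0B
TJ554	011002A330B
TJ557	2110023230A
TJ561	2A1001D100A
TJ562	ED302A0A10B
TJ567	31103D02200
TJ568	FA2041A2100
TJ572	42A00123201
TJ573	32200A2320B
TJ575	DD20D3AD10A
TJ582	F110DA0220A
TJ585	3320DA12001
TJ594	02002410001
TJ597	2120220D00B
TJ603	220012A2200
TJ606	D130AF2D00A
TJ608	0120B22DA0A
TJ609	A230AB2220A
TJ613	3D20032A000
TJ616	3B20A2BB10A
TJ629	421002A220A
TJ640	F3200421003
TJ653	2120DA3320A
TJ655	AD202A1020A
TJ663	03201A2320A
TJ667	2120222210A
TJ668	121032ABA0A
TJ669	2B20BA30D0A
TJ670	3330113020A
TJ671	01300320D0A
TJ676	A3002113A0A
TJ687	302011D020A
TJ690	23302422202
TJ692	B34022AD30A
TJ693	20200DA000A
TJ696	02101D3B200
TJ697	2200A03220A
TJ698	213023B2201
TJ699	3B3042D2A00
TJ701	23302D32A00
TJ703	D320AD32A0A
TJ727	3220402100A
TJ735	2222132D00A
TJ741	AD20AA2200B
TJ751	2230DD2D00B
TJ779	AA3122BD00A
TJ786	11311D2200A
TJ787	AAA12223001
TJ791	3D1121A200A
TJ794	D3111AAD00A
TJ802	0BA0022220A
TJ806	0A30022210A
TJ813	01A0A2D210A
TJ826	0FA0A32D10A
TJ832	0DA01DA020A
TJ837	0A40B2A010A
TJ852	03D0033D10A
TJ858	0230032020D
TJ861	0130D33010A
TJ867	02002233301
TJ873	0240012210B
TJ875	0DD0032210A
TJ882	BAA03D3100A
TJ890	2A2012A200A
TJ895	2A202A2A00A
TJ899	10303D2300A
TJ930	2C302FD200A
TJ932	2A30A020001
TJ938	2A10132000A
TJ942	31B0343300B
TJ944	2A102DB300A
TJ945	1D10302400A
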