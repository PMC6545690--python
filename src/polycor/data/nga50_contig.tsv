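condition	D1	D2	D3	D4	D5	D6	D7	D8	D9
Uncorrected	10876	5451	6325	50833	35924	40802	80752	85003	65138
ACE	11375	8475	3116	29126	20032	34273	55391	65163	62161
BFC	11672	9488	6307	49089	27365	40910	77526	78985	64709
BLESS2	9183	7737	2969	25133	17133	29968	61609	60574	55639
BrownieCorrector	13334	11015	6328	52152	38670	45400	83397	88877	71788
Karect	12507	10103	6295	54106	29286	41391	85226	85881	68873
Reckoner	9154	6440	6281	41977	26296	39605	58176	71724	56734
Karect+BrownieCorrector	13526	12409	6297	56046	30557	45423	89065	87822	74620
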