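condition	D1	D2	D3	D4	D5	D6	D7	D8	D9
Uncorrected	11377	5668	6419	60714	59591	41833	96381	109785	84659
ACE	12135	8597	3143	35425	40860	39895	62981	93602	83138
BFC	12294	9698	6392	59124	54093	41818	91577	110748	82101
BLESS2	10034	7909	3012	34856	36316	38431	73377	86526	74447
BrownieCorrector	14155	11570	6420	61474	65174	46678	96385	118192	96916
Karect	13528	10298	6377	63400	59526	42256	101753	124215	90661
Reckoner	9670	6509	6354	47781	50834	40779	67061	99419	71646
Karect+BrownieCorrector	14613	12795	6380	65857	62706	46332	103872	126449	104037
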