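species	inversion_start	inversion_end	inversion_length	repeat_lengths
Erodium carvifolium	30710	36608	5898	445
Erodium reichardii	5647	30221	24574	352
Erodium texanum	23425	46586	23161	3359
Drypetes longifolia	5605	89001	83396	1260
Drypetes hainanensis	5474	89321	83847	1191
Drypetes indica	5529	90486	84957	1047
Drypetes lateriflora	6031	90468	84437	1484
Drypetes similis	5716	89014	83298	1221
Drypetes diopa	5967	89759	83792	1357
Drypetes chevalieri	5917	90107	84190	1398
Passiflora capsularis	80769	112976	32207	791
Passiflora costaricensis	77218	114228	37010	1070
Passiflora costaricensis	77218	84722	7504	280
Taiwania cryptomerioides	7164	41842	34678	271
Glyptostrobus pensilis	46836	123831	76995	274
Sciadopitys verticillata	7855	47024	39169	157
Prumnopitys andina	32987	110212	77225	152
Picea abies	8507	32712	24205	395
Abies fargesii	7812	53059	45247	1176
Larix gmelinii	9126	51283	42157	411,44
Keteleeria davidiana	8159	50365	42206	610,66,15
Pinus armandii	49465	50435	970	232
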