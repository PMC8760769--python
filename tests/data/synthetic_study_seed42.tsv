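individual_id	group_id	phase	age_days	weight_start	weight_end	cortisol_baseline	cortisol_resp_1h	cortisol_resp_2h	rank_index
F101	group1	1	193.1702312475258	773.5	765.2	580.1797752841768	1846.152529895107	3575.8838521494436	0.03333333333333333
F101	group1	2	234.1702312475258	825.9	819.6	2085.9646432517625	2521.279471241319	3685.08895339513	0.06666666666666667
F102	group1	1	192.90538671117886	728.4	726.3	678.2027600319785	1809.145184530079	2337.6285045288637	0.9666666666666667
F102	group1	2	233.90538671117886	775.0	772.7	332.34517935286203	1464.9484370116468	2246.3483475476887	1.0
F103	group1	1	191.3232552120529	667.2	662.8	446.612450748893	714.0567686397143	1107.0629310386066	0.7
F103	group1	2	232.3232552120529	699.5	694.1	1336.1337442532263	1721.8190821592486	1439.034572581915	0.7333333333333333
F104	group1	1	165.22864684225064	711.3	705.5	1647.4480300306384	1471.898953157519	1590.8398534307437	0.5
F104	group1	2	206.22864684225064	739.7	719.8	447.292775302593	895.9879684231524	1193.1885417663511	0.36666666666666664
F105	group1	1	194.91417942321863	823.8	815.4	296.2175457969203	3900.201955564364	4819.18142028686	0.6333333333333333
F105	group1	2	235.91417942321863	891.8	876.7	1571.820497908428	2704.0585470450187	4707.824718414499	0.6333333333333333
F106	group1	1	159.05435065947256	681.1	676.8	2245.435764147957	708.1696731105816	847.726509569455	0.3
F106	group1	2	200.05435065947256	712.3	710.4	326.943560254593	741.0439225650879	669.2896226115726	0.16666666666666666
F201	group2	1	196.8448944117281	660.1	651.3	293.0076819873701	1835.7102080420113	3377.3139171598154	0.5
F201	group2	2	237.8448944117281	691.3	687.7	602.1111778508134	3675.3090960809063	2824.276438923582	0.4666666666666667
F202	group2	1	185.59353998904948	770.2	759.5	436.5191751685321	3588.242972425199	3691.2309650265775	0.3
F202	group2	2	226.59353998904948	769.0	751.5	691.4693278152405	3990.670548194023	3715.638825689092	0.2
F203	group2	1	157.9175344812534	620.6	618.1	2250.763305510479	1420.6102026534993	1773.554481425499	0.5
F203	group2	2	198.9175344812534	632.4	629.4	307.4402362602364	2253.132095073891	2484.7781622062835	0.6666666666666666
F204	group2	1	168.6337342151488	544.7	538.7	320.5341633271698	4736.751654985406	4044.406718309472	0.7666666666666667
F204	group2	2	209.6337342151488	577.8	573.1	1802.550917636452	1608.8864435387811	2445.5504092624983	0.8
F205	group2	1	177.64768712096898	763.3	749.6	1604.640343235324	959.6674268273802	1630.116686739252	0.9
F205	group2	2	218.64768712096898	804.9	784.8	1346.678654614726	1742.6112050143213	1166.1739168015717	0.8666666666666667
F206	group2	1	159.07108680034744	606.4	602.9	528.8452510581983	2123.0543589895465	2392.2615535937384	0.03333333333333333
F206	group2	2	200.07108680034744	628.9	625.0	2069.43147516046	2154.134178017687	1866.1730584390536	0.03333333333333333
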