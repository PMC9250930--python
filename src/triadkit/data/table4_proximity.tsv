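# SNP-to-gene proximity table transcribed from the published table.
# The source text of the table prints 65 marker rows although the accompanying prose reports 67 SNPs;
# no further rows are legible in the source, so 65 rows are transcribed and none are guessed.
# Gene tokens, positions and distances are kept exactly as printed (including range dashes and typographic
# variants such as 'TaNPF-3B4'); ranges use an en dash.
marker_id	chromosome	snp_position	genes	gene_positions	distances
AX94950355	1A	12918698	TaNPF6-1A1	14519757	1.601059
AX94815202	1A	14468156	TaNPF6-1A1	14519757	0.051601
AX94665912	1B	624080881	TaSLAC-1B10	622365197	1.715684
AX94923560	2A	729858424	TaCLC-2A2	740847366	10.988942
AX94906008	2A	737049474	TaCLC-2A2	740847366	3.797892
AX95162328	2A	745066946	TaCLC-2A2	740847366	4.21958
AX94601746	2B	745715147	TaCLC-2B2	742813858	2.901289
AX95203088	2B	748700718	TaCLC-2B2	742813858	5.88686
AX95190948	2B	752830609	TaCLC-2B2	742813858	10.016751
AX95189671	2D	394797805	TaNPF4-2D2, TaCLC-2D1	394118961, 395130092	0.332287, 0.678844
AX94829391	2D	601212191	TaCLC-2D2	608915455	7.703264
AX95142803	2D	601600533	TaCLC-2D2	608915455	7.314922
AX94799671	2D	608756380	TaCLC-2D2	608915455	0.159075
AX95142189	2D	609577225	TaCLC-2D2	608915455	0.66177
AX94786006	2D	610277424	TaCLC-2D2	608915455	1.361969
AX95148777	2D	641963392	TaNPF5-2D1-TaNPF5-2D5	639677529–643761743	1.798351–2.285863
AX95238274	3A	429463868	TaSLAC-3A4	421719078	7.74479
AX94593608	3A	671144035	TaNPF2-3A1, TaNPF2-3A2	660436466, 660507764	10.636271, 10.707569
AX95237615	3B	6378879	TaSLAC-3B1	7598907	1.220028
AX95259763	3B	229302401	TaSLAC-3B3	227663976	1.638425
AX95136655	3B	235865416	TaSLAC-3B3	227663976	8.20144
AX94723497	3B	236511642	TaSLAC-3B3, TaNPF3B1	227663976	8.847666
AX94561045	3B	642481079	TaNPF5-3B3–TaNPF5-3B10, TaCLC-3B3	651425224–655435367	8.944145–12.954288
AX94539428	3B	657947249	TaCLC-3B3, TaNPF5-3B3–TaNPF5-3B10, TaNPF-3B4, TaNPF-3B5	651425224–662795946	2.511882–6.522025
AX94386613	3B	658604225	TaCLC-3B3, TaNPF5-3B3–TaNPF5-3B10, TaNPF-3B4, TaNPF-3B5	651425224–662795946	3.168858–7.179001
AX94418180	3B	659275308	TaCLC-3B3, TaNPF5-3B3–TaNPF5-3B10, TaNPF-3B4, TaNPF-3B5	651425224–662795946	3.839941–7.850084
AX94429243	3B	659787974	TaCLC-3B3, TaNPF5-3B3–TaNPF5-3B10, TaNPF-3B4, TaNPF-3B5	651425224–662795946	4.352607–8.36275
AX94910184	3D	352948426	TaCLC-3D1, TaNRT2-3D1	355885478, 356623041	2.937052, 3.674615
AX94514369	4A	544201715	TaNPF4-4A1	533257983	10.943732
AX94926692	4A	544202284	TaNPF4-4A1	533257983	10.944301
AX94766675	4A	575009572	TaNPF8-4A6	575006132	0.00344
AX94400142	4A	581754986	TaCLC-4A1, TaNPF2-4A1, TaNPF7-4A1, TaNPF8-4A7, TaNPF8-4A8	585431883–593113134	3.676897–11.358148
AX94414780	4B	25929732	TaCLC-4B1, TaNPF2-4B1, TaNPF4B1	20278828–25842359	5.650904
AX94478236	4B	28716503	TaCLC-4B1, TaNPF2-4B1, TaNPF4B1	20278828–25842359	2.874144–8.437675
AX94997694	4B	34789538	TaCLC-4B1, TaNPF2-4B1, TaNPF4B1	20278828–25842359	8.947179–14.51071
AX94517352	4D	21886662	TaCLC-4D1, TaNPF2-4D1, TaNPF8-4D1	10764927–15356868	6.529794–11.121735
AX94586364	4D	22947854	TaCLC-4D1, TaNPF2-4D1, TaNPF8-4D1	10764927–15356868	7.590986–12.182927
AX94914919	4D	28974006	TaNPF8-4D2	28481269	0.492737
AX94738199	5D	10899555	TaNPF2-5D1	6820550	4.079005
AX95110067	5D	467774783	TaNPF4-5D3	464415850	3.358933
AX95002541	5D	468689841	TaNPF4-5D3	464415850	4.273991
AX95132327	5D	472234562	TaNPF4-5D3	464415850	7.818712
AX94631745	5D	528728651	TaNPF5-5D1—TaNPF5-5D3	528294425–528587054	0.141597–0.43423
AX94803288	6A	14353974	TaNRT2-6A1- TaNRT2-6A13	15727844–16408185	1.37387–2.054211
AX95017906	6A	23433182	TaNRT2-6A14	21634811	1.798371
AX94983341	6A	28412753	TaNRT2-6A14	21634811	6.777942
AX95210745	6A	29967076	TaNRT2-6A14	21634811	8.332265
AX94510892	6A	112585030	TaNPF8-6A1	117412062	4.827032
AX94534539	6A	497462168	TaNPF7-6A1	486547388	10.91478
AX94573487	6D	27978202	TaNPF5-6D1	22172543	5.805659
AX94415776	6D	28700804	TaNPF5-6D1	22172543	6.528261
AX94978974	6D	29876083	TaNPF5-6D1	22172543	7.70354
AX94737868	6D	29876631	TaNPF5-6D1	22172543	7.704088
AX95250225	6D	29928065	TaNPF5-6D1	22172543	7.755522
AX94461279	6D	451183032	TaNPF8-6D2	449226044	1.956988
AX94665619	7A	222939896	TaCLC-7A1	216343576	6.59632
AX94566038	7A	683488235	TaNPF5-7A3	692626752	9.138517
AX95178548	7B	112337703	TaNPF5-7B2	116046396	3.708693
AX94532247	7B	524619772	TaNPF8-7B1- TaNPF8-7B3	517623485–518338133	6.281639–6.996287
AX94424632	7B	562740463	TaNPF8-7B4–TaNPF8-7B6	556686657–558639959	4.100504–6.053806
AX94880654	7B	592345313	TaNRT2-7B1	583923053	8.42226
AX94553632	7B	633318727	TaNPF5-7B4	624468356	8.850371
AX94781629	7D	206695834	TaCLC-7D1	204246408	2.449426
AX94678472	7D	487753483	TaNPF8-7D2–TaNPF8-7D4	489153269–489673028	1.39978–1.91954
AX95080011	7D	592191388	TaNPF5-7D4	600836846	8.645458
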