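chrom	pos	ref	alt
chr1	21964	G	C
chr1	210397	C	G
chr1	392848	C	T
chr1	518470	C	G
chr1	572308	G	T
chr1	872405	C	G
chr1	880381	A	G
chr1	921258	A	G
chr1	972105	C	A
chr1	1021955	T	C
chr1	1037907	T	C
chr1	1053859	T	A
chr1	1275193	G	A
chr1	1327037	C	A
chr1	1353956	A	C
chr1	1402809	G	C
chr1	1869405	A	G
chr1	1885357	C	A
chr1	1964120	A	T
chr1	1987051	A	G
chr1	2199412	G	T
chr1	2239292	T	A
chr1	2258235	T	C
chr1	2336998	C	G
chr1	2412770	T	A
chr1	2623137	G	T
chr1	2684951	G	A
chr1	2773684	A	G
chr1	2829516	C	G
chr1	3003991	G	T
chr1	3050850	A	G
chr1	3123631	T	A
chr1	3146562	T	G
chr1	3260220	C	G
chr1	3307079	G	T
chr1	3374875	T	A
chr1	3380857	A	G
chr1	3430707	T	A
chr1	3437686	G	A
chr1	3508473	C	G
chr1	3649050	T	C
chr1	3862408	C	T
chr1	3903285	G	C
chr1	3949147	C	G
chr1	3973075	C	A
chr1	4158517	G	T
chr1	4259214	A	C
chr1	4307070	C	G
chr1	4355923	G	A
chr1	4390818	T	A
chr1	4440668	C	A
chr1	4465593	C	A
chr1	4492512	A	C
chr1	4599191	G	A
chr1	4732789	G	A
chr1	4752729	T	G
chr1	4767684	T	G
chr1	4774663	T	A
chr1	4785630	T	G
chr1	4938171	T	A
chr2	37916	C	T
chr2	51874	C	G
chr2	120667	G	T
chr2	157556	C	T
chr2	384872	C	G
chr2	387863	T	C
chr2	522458	G	A
chr2	817570	T	A
chr2	867420	T	A
chr2	937210	G	C
chr2	965126	C	A
chr2	984069	A	G
chr2	1013979	T	G
chr2	1037907	C	G
chr2	1071805	C	A
chr2	1095733	A	C
chr2	1302112	G	C
chr2	1471602	C	A
chr2	1495530	T	G
chr2	1572299	G	T
chr2	1641092	C	T
chr2	1657044	G	C
chr2	1830522	C	G
chr2	1926234	C	G
chr2	2023940	C	T
chr2	2074787	T	A
chr2	2245274	C	T
chr2	2418752	A	T
chr2	2520446	T	G
chr2	2615161	C	A
chr2	2922237	G	T
chr2	2933204	A	T
chr2	2979066	T	A
chr2	3183451	G	T
chr2	3208376	G	A
chr2	3215355	T	G
chr2	3321037	G	T
chr2	3322034	G	A
chr2	3565302	C	G
chr2	3639080	T	G
chr2	3676966	C	G
chr2	3781651	T	C
chr2	3789627	A	C
chr2	4106673	A	G
chr2	4268187	T	C
chr2	4308067	A	C
chr2	4375863	A	T
chr2	4461605	C	G
chr2	4488524	A	C
chr2	4529401	T	A
chr3	84775	A	T
chr3	139610	C	T
chr3	251274	G	C
chr3	281184	G	A
chr3	330037	G	C
chr3	335022	T	G
chr3	386866	C	T
chr3	389857	A	C
chr3	511491	G	C
chr3	635119	G	C
chr3	652068	G	A
chr3	674999	C	T
chr3	767720	C	A
chr3	940201	A	C
chr3	1081775	G	C
chr3	1121655	G	T
chr3	1140598	A	G
chr3	1211385	T	G
chr3	1288154	A	C
chr3	1360935	G	C
chr3	1448671	A	T
chr3	1517464	G	A
chr3	1676984	T	G
chr3	1926234	T	G
chr3	2161526	C	T
chr3	2341983	T	G
chr3	2610176	T	G
chr3	2704891	G	A
chr3	2734801	A	T
chr3	2831510	T	C
chr3	3000003	G	T
chr3	3136592	C	T
chr3	3236292	G	T
chr3	3271187	T	A
chr3	3461614	T	A
chr3	3524425	C	G
chr3	3701891	A	G
chr3	3718840	A	G
chr3	4161508	A	C
chr3	4199394	A	C
chr3	4303082	A	C
chr3	4408764	C	A
chr3	4517437	A	T
chr3	4679948	T	A
chr3	4795600	A	T
chr4	176499	T	C
chr4	203418	G	A
chr4	446686	A	T
chr4	566326	T	A
chr4	602218	A	T
chr4	643095	C	G
chr4	806603	G	T
chr4	1086760	C	T
chr4	1132622	A	C
chr4	1160538	A	G
chr4	1260238	A	C
chr4	1434713	C	A
chr4	1479578	G	A
chr4	1663026	G	C
chr4	1739795	A	G
chr4	1834510	A	G
chr4	1871399	T	G
chr4	2038895	T	A
chr4	2122643	C	A
chr4	2132613	G	C
chr4	2208385	C	G
chr4	2297118	T	G
chr4	2511473	G	A
chr4	2732807	T	C
chr4	2755738	G	A
chr4	2776675	A	T
chr4	2987042	T	A
chr4	2999006	T	G
chr4	3354935	G	T
chr4	3420737	C	A
chr4	3455632	A	G
chr4	3828510	C	T
chr4	4036883	T	A
chr4	4040871	A	C
chr4	4125616	G	A
chr4	4299094	A	G
chr4	4445653	C	A
chr4	4470578	A	G
chr4	4545353	A	C
chr4	4585233	A	T
chr4	4605173	T	C
chr4	4732789	A	T
chr4	4775660	G	C
chr4	4813546	A	T
chr4	4888321	A	G
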