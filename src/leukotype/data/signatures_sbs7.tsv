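context	SBS1	SBSblood	SBS5like	SBS9	SBS18	MMRlike	thioMMR
A[C>A]A	0.001968	0.003038	0.010962	0.001218	0.053324	0.004353	0.001640
A[C>A]C	0.002046	0.002932	0.012015	0.001258	0.057728	0.004137	0.001561
A[C>A]G	0.002023	0.002955	0.011199	0.001275	0.056188	0.004386	0.001520
A[C>A]T	0.002091	0.003075	0.011649	0.001232	0.055790	0.004498	0.001509
C[C>A]A	0.002003	0.002957	0.011179	0.001243	0.056713	0.004105	0.001587
C[C>A]C	0.001972	0.002932	0.009546	0.001264	0.053106	0.004270	0.001639
C[C>A]G	0.002021	0.003115	0.011356	0.001263	0.051178	0.004251	0.001611
C[C>A]T	0.002081	0.002893	0.011434	0.001268	0.054222	0.004316	0.001576
G[C>A]A	0.001997	0.003062	0.009166	0.001233	0.053598	0.004154	0.001680
G[C>A]C	0.002044	0.002962	0.010278	0.001219	0.052800	0.004202	0.001604
G[C>A]G	0.002067	0.003115	0.011253	0.001226	0.055562	0.004249	0.001620
G[C>A]T	0.002007	0.002965	0.012023	0.001164	0.053016	0.004264	0.001639
T[C>A]A	0.002061	0.002945	0.010609	0.001271	0.055408	0.004325	0.001550
T[C>A]C	0.001973	0.003276	0.009044	0.001267	0.056267	0.004429	0.001633
T[C>A]G	0.002042	0.002953	0.009670	0.001261	0.055175	0.004244	0.001499
T[C>A]T	0.002088	0.003066	0.010389	0.001263	0.052478	0.004371	0.001574
A[C>G]A	0.002111	0.002757	0.010251	0.001297	0.001594	0.004397	0.001639
A[C>G]C	0.002016	0.003056	0.010266	0.001266	0.001603	0.004341	0.001546
A[C>G]G	0.002057	0.002982	0.010369	0.001280	0.001545	0.004542	0.001653
A[C>G]T	0.002097	0.003070	0.010154	0.001260	0.001624	0.004457	0.001683
C[C>G]A	0.002081	0.003003	0.010632	0.001253	0.001552	0.004277	0.001555
C[C>G]C	0.002008	0.003006	0.012336	0.001246	0.001593	0.004409	0.001698
C[C>G]G	0.002047	0.003004	0.010602	0.001259	0.001495	0.004409	0.001637
C[C>G]T	0.002001	0.003006	0.010955	0.001221	0.001608	0.004534	0.001576
G[C>G]A	0.002041	0.003023	0.010278	0.001304	0.001593	0.004392	0.001608
G[C>G]C	0.002035	0.003075	0.009508	0.001190	0.001604	0.004346	0.001705
G[C>G]G	0.002034	0.003126	0.009935	0.001271	0.001553	0.004155	0.001610
G[C>G]T	0.001989	0.002950	0.010266	0.001255	0.001627	0.004365	0.001531
T[C>G]A	0.002046	0.003038	0.009882	0.001192	0.001561	0.004244	0.001576
T[C>G]C	0.002014	0.003110	0.009690	0.001251	0.001577	0.004473	0.001610
T[C>G]G	0.002073	0.003021	0.009815	0.001209	0.001618	0.004204	0.001590
T[C>G]T	0.001962	0.002880	0.011343	0.001319	0.001640	0.004125	0.001657
A[C>T]A	0.002092	0.036913	0.009711	0.001322	0.001624	0.024445	0.041919
A[C>T]C	0.001952	0.034742	0.009643	0.001241	0.001580	0.024788	0.001608
A[C>T]G	0.204523	0.036072	0.010520	0.001317	0.001600	0.024749	0.100245
A[C>T]T	0.002051	0.036331	0.010400	0.001280	0.001665	0.023714	0.069127
C[C>T]A	0.001954	0.036851	0.010302	0.001267	0.001608	0.024865	0.041584
C[C>T]C	0.001972	0.035203	0.008952	0.001268	0.001593	0.024282	0.001590
C[C>T]G	0.205281	0.036632	0.010454	0.001308	0.001595	0.023333	0.097348
C[C>T]T	0.002114	0.037525	0.011005	0.001280	0.001589	0.024592	0.079309
G[C>T]A	0.002088	0.037022	0.010115	0.001298	0.001617	0.022969	0.042193
G[C>T]C	0.002121	0.038575	0.009827	0.001269	0.001627	0.023953	0.001675
G[C>T]G	0.204116	0.033949	0.010206	0.001284	0.001575	0.022845	0.099946
G[C>T]T	0.002072	0.037697	0.011771	0.001339	0.001610	0.024012	0.075963
T[C>T]A	0.001916	0.036739	0.012101	0.001195	0.001580	0.023658	0.040469
T[C>T]C	0.001988	0.038348	0.009499	0.001198	0.001571	0.023801	0.001718
T[C>T]G	0.199313	0.037535	0.009501	0.001257	0.001584	0.021510	0.100909
T[C>T]T	0.001954	0.034950	0.010653	0.001178	0.001646	0.023429	0.075744
A[T>A]A	0.002012	0.003059	0.012413	0.001203	0.001625	0.004430	0.001652
A[T>A]C	0.002047	0.002797	0.009495	0.001299	0.001623	0.004273	0.001594
A[T>A]G	0.001975	0.003112	0.009474	0.001231	0.001554	0.004269	0.001628
A[T>A]T	0.002125	0.003064	0.010667	0.001235	0.001610	0.004333	0.001537
C[T>A]A	0.002024	0.003099	0.010119	0.001273	0.001583	0.004186	0.001690
C[T>A]C	0.002098	0.003024	0.009958	0.001242	0.001600	0.004277	0.001655
C[T>A]G	0.002006	0.002971	0.010538	0.001296	0.001670	0.004383	0.001682
C[T>A]T	0.002073	0.002974	0.009959	0.001235	0.001520	0.004281	0.001575
G[T>A]A	0.002072	0.003014	0.010103	0.001229	0.001560	0.004157	0.001639
G[T>A]C	0.002066	0.003099	0.011157	0.001259	0.001575	0.004169	0.001689
G[T>A]G	0.001965	0.002896	0.010583	0.001244	0.001530	0.004440	0.001621
G[T>A]T	0.002085	0.002878	0.009608	0.001322	0.001588	0.004168	0.001639
T[T>A]A	0.001978	0.002928	0.011076	0.001231	0.001536	0.004303	0.001621
T[T>A]C	0.001994	0.003115	0.012012	0.001258	0.001594	0.004440	0.001620
T[T>A]G	0.001973	0.003277	0.010457	0.001248	0.001551	0.004193	0.001539
T[T>A]T	0.002064	0.002803	0.010091	0.001274	0.001497	0.004376	0.001560
A[T>C]A	0.002016	0.013644	0.009785	0.019653	0.001571	0.021076	0.001565
A[T>C]C	0.001943	0.013870	0.009934	0.020437	0.001545	0.021853	0.001595
A[T>C]G	0.002045	0.014164	0.010688	0.020554	0.001576	0.021154	0.001644
A[T>C]T	0.002094	0.013460	0.010942	0.021166	0.001554	0.021504	0.001588
C[T>C]A	0.001999	0.013544	0.010928	0.020764	0.001598	0.019882	0.001613
C[T>C]C	0.001983	0.013976	0.010494	0.020627	0.001640	0.021555	0.001610
C[T>C]G	0.002028	0.014058	0.010097	0.019950	0.001629	0.021129	0.001505
C[T>C]T	0.002075	0.013811	0.009776	0.020760	0.001559	0.022723	0.001635
G[T>C]A	0.002052	0.015031	0.010204	0.020882	0.001684	0.020863	0.001575
G[T>C]C	0.002125	0.014356	0.010480	0.019688	0.001575	0.020765	0.001597
G[T>C]G	0.002044	0.013666	0.009504	0.020820	0.001565	0.022448	0.001587
G[T>C]T	0.002114	0.013723	0.010021	0.021133	0.001568	0.021780	0.001562
T[T>C]A	0.002014	0.013516	0.010922	0.020878	0.001659	0.021679	0.001620
T[T>C]C	0.002049	0.014001	0.009729	0.020247	0.001653	0.021764	0.001599
T[T>C]G	0.001991	0.013710	0.009609	0.019632	0.001554	0.021686	0.001651
T[T>C]T	0.002027	0.013816	0.010838	0.019824	0.001638	0.021434	0.001656
A[T>G]A	0.002035	0.002993	0.009628	0.036509	0.001613	0.004367	0.001633
A[T>G]C	0.001904	0.002962	0.008567	0.036714	0.001630	0.004333	0.001599
A[T>G]G	0.001986	0.002917	0.010890	0.038888	0.001590	0.004518	0.001574
A[T>G]T	0.002038	0.002890	0.008551	0.036549	0.001590	0.004201	0.001615
C[T>G]A	0.002009	0.002978	0.009906	0.035898	0.001657	0.004086	0.001586
C[T>G]C	0.002070	0.003083	0.010960	0.037683	0.001625	0.004244	0.001665
C[T>G]G	0.002048	0.003015	0.012003	0.037359	0.001559	0.004210	0.001659
C[T>G]T	0.001986	0.002881	0.011541	0.037025	0.001552	0.004310	0.001632
G[T>G]A	0.001982	0.002882	0.010412	0.036350	0.001626	0.004517	0.001569
G[T>G]C	0.001933	0.003090	0.011475	0.038379	0.001539	0.004363	0.001557
G[T>G]G	0.002086	0.003035	0.009763	0.036492	0.001636	0.004204	0.001654
G[T>G]T	0.002028	0.003135	0.009747	0.034904	0.001611	0.004305	0.001620
T[T>G]A	0.001986	0.003015	0.011102	0.037805	0.001607	0.004403	0.001575
T[T>G]C	0.002033	0.003051	0.010293	0.036299	0.001569	0.004326	0.001534
T[T>G]G	0.002033	0.003162	0.010428	0.037259	0.001569	0.004219	0.001633
T[T>G]T	0.002084	0.003022	0.010359	0.038491	0.001637	0.004251	0.001687
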