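chrom	start	end	n_snp	expected_length	start_snp	end_snp
1	24685742	25641524	174	955783	rs195704	rs10903129
1	111171895	111330302	39	158408	rs343769	rs947633
1	111345660	118691338	1454	7345679	rs12038954	rs7535961
1	118704719	143649677	333	24944959	rs10923556	rs2500347
1	144148243	144975558	40	827316	rs2236566	rs12122100
1	156202557	165715016	2338	9512460	rs16839492	rs7518703
1	201467879	204068495	606	2600617	rs6672661	rs1361754
1	204074127	214016229	2022	9942103	rs954206	rs7549052
2	143712980	143772718	16	59739	rs4371294	rs12328672
3	71274040	71332365	26	58326	rs4677532	rs7374975
3	188567203	189810377	350	1243175	rs6797770	rs3732909
3	189812552	191786499	536	1973948	rs9824282	rs6444435
5	179518398	179998061	106	479664	rs6897922	rs4700745
5	180003882	180623543	95	619662	rs11960332	rs1279912
8	13440994	15451587	1070	2010594	rs1160220	rs919401
8	15464497	17859195	885	2394699	rs12547525	rs208753
8	17881369	18740036	391	858668	rs10503606	rs6982585
10	53836193	58170063	976	4333871	rs11001909	rs10825864
10	58698423	63455095	941	4756673	rs2393230	rs10821944
10	109396522	114694771	1012	5298250	rs11193576	rs17746916
12	14293625	17541979	550	3248355	rs17834211	rs1553115
12	17545101	28831294	2813	11286194	rs10840729	rs7311230
12	130049943	132288869	432	2238927	rs7135850	rs7975069
13	59004926	61882091	525	2877166	rs1622710	rs11838572
13	62305059	66409431	620	4104373	rs9598515	rs9540948
13	66611634	73911046	1636	7299413	rs7336017	rs9573384
13	73937508	77639621	839	3702114	rs9318278	rs2254690
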