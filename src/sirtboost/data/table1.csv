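patient,alone_mld_gy,alone_ntcp_pct,alone_cv15_cc,alone_ptv_cc,alone_flagged,boost_mld_gy,boost_ntcp_pct,boost_cv15_cc,boost_ptv_cc,boost_flagged,lesions_targeted,lesions_total
1,10.4,0.1,1589,174,True,8.0,0.0,1860,90,False,3,5
2,6.0,0.0,1156,69,False,5.6,0.0,1155,44,False,1,1
3,17.6,97.5,1305,564,True,13.9,9.8,1626,282,True,5,5
4,10.6,0.4,1011,162,True,8.6,0.0,1124,72,False,4,4
5,11.5,0.6,1643,257,True,7.1,0.0,2000,59,False,1,2
6,2.8,0.0,1295,15,False,NA,NA,NA,NA,NA,0,1
7,5.5,0.0,1900,42,False,4.1,0.0,2004,29,False,2,3
8,8.0,0.0,916,133,False,6.8,0.0,976,78,False,2,2
9,4.5,0.0,1016,20,False,4.5,0.0,1016,20,False,1,1
10,8.6,0.0,1423,392,False,7.6,0.0,1456,195,False,1,2
11,7.1,0.0,878,26,False,NA,NA,NA,NA,NA,0,1
12,8.7,0.0,1498,168,False,8.5,0.0,1484,154,False,4,4
13,2.1,0.0,1715,41,False,NA,NA,NA,NA,NA,0,1
14,6.7,0.0,1405,122,False,NA,NA,NA,NA,NA,0,1
15,17.6,98.3,750,342,True,9.5,0.0,1216,151,True,2,5
16,11.8,0.5,1116,246,True,11.2,0.1,1163,205,True,3,3
17,11.4,0.2,971,76,True,NA,NA,NA,NA,NA,0,3
18,10.7,1.8,2028,1195,True,9.3,0.1,2174,997,True,1,1
19,8.2,0.0,1222,62,False,4.6,0.0,1418,23,False,1,3
20,8.1,0.1,1367,250,False,NA,NA,NA,NA,NA,0,1
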