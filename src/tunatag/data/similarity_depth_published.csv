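fish_id,block,corr_min,corr_max,dissimilar_day_1,dissimilar_day_2,mean_rank_days_1_7,altered_first_week
16P1231,first30,-0.27,0.29,25,27,18,False
16P2365,first30,-0.25,0.33,4,25,8,True
17P1004,first30,-0.27,0.21,2,28,15,True
18P0812,first30,-0.23,0.32,27,30,14,False
18P0837,first30,-0.17,0.44,4,12,14,False
18P0932,first30,-0.12,0.48,3,9,8,True
19P0137,first30,-0.18,0.53,20,29,21,False
19P0206,first30,-0.26,0.33,3,5,9,True
20P0084,first30,-0.26,0.11,23,24,18,False
20P1136,first30,-0.11,0.18,16,24,18,False
20P1137,first30,-0.08,0.34,15,21,17,False
21P0468,first30,-0.31,0.43,20,21,23,False
18P0837,last30,-0.17,0.60,12,26,11,
19P0206,last30,0.27,0.84,1,2,13,
20P0084,last30,0.29,0.72,9,10,12,
20P1136,last30,0.35,0.54,9,10,14,
20P1137,last30,0.18,0.26,4,11,14,
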