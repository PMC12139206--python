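fish_id,block,corr_min,corr_max,dissimilar_day_1,dissimilar_day_2,mean_rank_days_1_7,altered_first_week
16P1231,first30,-0.35,0.39,2,21,13,True
16P2365,first30,-0.31,0.44,20,21,17,False
17P1004,first30,-0.30,0.28,13,21,18,False
18P0812,first30,-0.22,0.50,1,7,9,True
18P0837,first30,-0.16,0.29,12,14,16,False
18P0932,first30,-0.35,0.54,1,6,9,True
19P0137,first30,-0.14,0.20,20,29,19,False
19P0206,first30,-0.31,0.30,5,15,9,True
20P0084,first30,-0.33,0.55,4,5,8,True
20P1136,first30,-0.37,0.39,2,4,5,True
20P1137,first30,-0.08,0.45,3,5,8,True
21P0468,first30,-0.18,0.76,3,4,6,True
17P1004,last30,-0.09,0.53,20,21,16,
18P0837,last30,0.38,0.71,17,30,19,
19P0206,last30,0.48,0.82,19,27,14,
20P0084,last30,0.54,0.80,1,9,11,
20P1136,last30,0.38,0.81,17,18,20,
20P1137,last30,-0.07,0.76,18,21,16,
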