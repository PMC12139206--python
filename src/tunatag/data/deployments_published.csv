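fish_id,tag_type,sampling_hz,deployment_date,deployment_days,displacement_km,popup_distance_km,curved_fork_length_cm,est_weight_kg,fight_time_min,tow_time
16P1231,MiniPAT,0.2,2019-08-23,265,11417,1208,212,148,15,03:22
16P2365,MiniPAT,0.2,2019-08-25,121,3649,682,199,116,11,04:11
17P1004,MiniPAT,0.2,2019-09-03,365,16224,135,203,134,12,04:59
18P0812,MiniPAT,0.2,2018-11-02,278,13432,288,175,81,18,NR
18P0837,MiniPAT,0.2,2019-09-02,365,15745,794,181,90,15,03:33
18P0932,MiniPAT,0.2,2019-10-23,337,14134,35,238,211,34,03:11
19P0137,MiniPAT,0.2,2019-11-18,314,8964,77,166,80,NA,NR
19P0206,MiniPAT,0.2,2019-10-02,362,19599,7,221,141,28,05:40
20P0084,MiniPAT,0.2,2020-09-09,362,14145,44,229,155,12.67,04:59
20P1136,MiniPAT,0.2,2020-09-12,365,15733,193,194,107,12.68,05:03
20P1137,MiniPAT,0.2,2020-09-16,359,14520,197,201,129,18,07:16
21P0468,MiniPAT,0.2,2021-09-04,110,2016,224,153,51,10.88,NR
A15884,G7,30,2019-09-08,3.93,380,NA,193,113,10,NR
A17240,G7,20,2020-09-09,1.85,17,5,196,98,11.12,03:08
A17247,G7,20,2020-09-09,0.89,17,2,205,127,15,04:46
A17248,G7,30,2019-10-21,2.15,17,7,212,152,30,NR
A17890,G7,20,2020-09-11,3.73,17,2,212,124,10,01:16
A17891,G7,20,2020-09-15,3.64,17,3,204,131,10,03:00
A17893,G7,20,2020-09-13,3,11,3,207,149,30,05:52
A17939,G7,20,2021-11-15,3.68,15,8,185,98,10,03:54
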