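subject,bone,length,width,height,surface_area,volume
Basketball player 1,metatarsal,1.0000,1.0888,1.1298,1.1622,1.2792
Basketball player 1,proximal_phalanx,1.0469,0.8809,1.0726,1.1539,1.3140
Basketball player 1,distal_phalanx,0.8624,0.5775,0.9011,1.1234,1.1250
Basketball player 2,metatarsal,1.0000,1.0810,1.1339,1.1678,1.2790
Basketball player 2,proximal_phalanx,1.0222,0.9682,1.1093,1.1493,1.2942
Basketball player 2,distal_phalanx,0.7899,0.7332,0.9258,1.1057,1.0810
Basketball player 3,metatarsal,1.0000,1.2836,1.3411,1.3858,1.7278
Basketball player 3,proximal_phalanx,1.0504,1.3530,1.2023,1.4153,1.6953
Basketball player 3,distal_phalanx,0.6676,0.6450,0.8442,1.0831,1.1752
Basketball player 4,metatarsal,1.0000,1.2828,1.3473,1.3787,1.6984
Basketball player 4,proximal_phalanx,1.0189,1.4094,1.1505,1.4003,1.6632
Basketball player 4,distal_phalanx,0.6445,0.6919,0.8321,1.0673,1.1392
Badminton player 1,metatarsal,1.0000,1.2233,1.3435,1.3942,1.7969
Badminton player 1,proximal_phalanx,1.1075,1.0921,1.1640,1.4185,1.7623
Badminton player 1,distal_phalanx,0.7548,0.8613,0.9659,1.2927,1.3370
Badminton player 2,metatarsal,1.0000,1.2233,1.3168,1.3947,1.7916
Badminton player 2,proximal_phalanx,1.1135,0.9260,1.1023,1.4127,1.7526
Badminton player 2,distal_phalanx,0.8457,0.7225,0.9500,1.3040,1.3527
Jumper,metatarsal,1.0000,1.1413,1.1301,1.1605,1.3141
Jumper,proximal_phalanx,0.9830,1.1497,0.9508,1.1437,1.2478
Jumper,distal_phalanx,0.7501,0.7890,0.8570,1.0704,1.0186
Wrestler,metatarsal,1.0000,1.2051,1.3740,1.3188,1.6124
Wrestler,proximal_phalanx,1.0654,1.1936,1.1835,1.3299,1.5755
Wrestler,distal_phalanx,0.8693,0.7071,0.8923,1.2735,1.3800
Volleyball,metatarsal,1.0000,1.1245,1.2219,1.1722,1.3143
Volleyball,proximal_phalanx,1.0037,1.2308,1.1172,1.1285,1.1912
Volleyball,distal_phalanx,0.5197,0.8508,0.7003,0.8715,0.7983
Runner,metatarsal,1.0000,1.0825,1.1205,1.1398,1.2833
Runner,proximal_phalanx,1.0535,1.0978,1.0544,1.1460,1.2460
Runner,distal_phalanx,0.7852,0.5084,0.8214,0.9570,0.8942
H. naledi,metatarsal,1.0000,1.0000,1.0000,1.0000,1.0000
H. naledi,proximal_phalanx,1.0000,1.0000,1.0000,1.0000,1.0000
H. naledi,distal_phalanx,1.0000,1.0000,1.0000,1.0000,1.0000
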