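subject,bone,length,width,height,surface_area,volume
Basketball player 1,metatarsal,100.00,43.54,32.99,9684.50,52171.00
Basketball player 1,proximal_phalanx,50.46,31.07,41.20,4193.20,17466.58
Basketball player 1,distal_phalanx,36.61,22.06,38.00,2524.30,8159.31
Basketball player 2,metatarsal,100.00,43.23,33.11,9731.10,52165.56
Basketball player 2,proximal_phalanx,49.27,34.15,42.61,4176.39,17202.76
Basketball player 2,distal_phalanx,33.53,28.01,39.04,2484.64,7839.71
Basketball player 3,metatarsal,100.00,51.33,39.16,11547.93,70468.14
Basketball player 3,proximal_phalanx,50.63,47.72,46.18,5142.94,22534.32
Basketball player 3,distal_phalanx,28.34,24.64,35.60,2433.78,8523.04
Basketball player 4,metatarsal,100.00,51.30,39.34,11488.95,69268.92
Basketball player 4,proximal_phalanx,49.11,49.71,44.19,5088.57,22108.22
Basketball player 4,distal_phalanx,27.36,26.43,35.09,2398.16,8262.04
Badminton player 1,metatarsal,100.00,48.92,39.23,11617.66,73287.57
Badminton player 1,proximal_phalanx,53.38,38.52,44.71,5154.73,23424.27
Badminton player 1,distal_phalanx,32.04,32.90,40.73,2904.84,9696.46
Badminton player 2,metatarsal,100.00,48.92,38.45,11622.25,73069.31
Badminton player 2,proximal_phalanx,53.67,32.66,42.34,5133.38,23296.07
Badminton player 2,distal_phalanx,35.90,27.60,40.06,2930.24,9810.71
Jumper,metatarsal,100.00,45.64,33.00,9670.03,53595.01
Jumper,proximal_phalanx,47.38,40.55,36.52,4156.07,16586.19
Jumper,distal_phalanx,31.84,30.14,36.14,2405.28,7387.71
Wrestler,metatarsal,100.00,48.19,40.12,10989.32,65759.84
Wrestler,proximal_phalanx,51.35,42.10,45.46,4832.74,20941.93
Wrestler,distal_phalanx,36.90,27.01,37.63,2861.60,10008.66
Volleyball,metatarsal,100.00,44.97,35.68,9767.82,53604.66
Volleyball,proximal_phalanx,48.38,43.41,42.91,4100.92,15833.66
Volleyball,distal_phalanx,22.06,32.50,29.53,1958.38,5789.57
Runner,metatarsal,100.00,43.29,32.72,9497.87,52340.88
Runner,proximal_phalanx,50.78,38.72,40.50,4164.21,16562.12
Runner,distal_phalanx,33.33,19.42,34.64,2150.35,6485.48
H. naledi,metatarsal,100.00,39.99,29.20,8332.98,40784.73
H. naledi,proximal_phalanx,48.20,35.27,38.41,3633.81,13292.19
H. naledi,distal_phalanx,42.45,38.20,42.17,2247.04,7252.54
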