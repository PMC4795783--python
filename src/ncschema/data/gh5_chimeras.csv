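name,code,E,m,TA50,TA50_err,T50,T50_err,A_re,A_re_err,group
P1,11111111,0,0,80,0.9,79,0.4,1.17,0.06,parent
P2,22222222,0,0,64,0.6,72,0.3,1.00,,parent
C1,22211111,10,51,62,0.5,69,0.5,1.21,0.07,sampled
C2,22112111,7,52,50,0.6,67,0.4,0.94,0.05,sampled
C3,11111222,9,52,64,0.7,66,1.0,0.92,0.06,sampled
C4,22111211,14,55,64,0.6,68,0.9,0.84,0.05,sampled
C5,21111111,8,21,64,0.9,77,0.8,1.42,0.07,sampled
C6,11111121,9,24,60,1.0,68,0.6,1.34,0.08,sampled
C7,22111111,6,41,58,1.1,64,1.2,1.35,0.06,sampled
C8,22221111,8,63,68,0.9,80,1.4,1.23,0.06,sampled
C9,11222211,22,51,67,1.2,76,1.1,1.18,0.04,designed
C10,11221211,21,40,76,1.1,83,0.8,1.43,0.09,designed
C11,11221111,12,26,70,0.6,81,0.9,1.40,0.07,designed
C12,21222222,11,20,70,0.4,74,0.5,1.37,0.06,designed
C13,22221222,0,11,71,1.0,73,0.6,1.39,0.04,designed
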