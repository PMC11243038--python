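label,position_frame_cm,position_avg_cm,stddev_cm,raman_1064,rr_266,rr_210,factor_266,factor_210
rho_CH3_M1,1050,1049,5,5.07e-10,0.0023,0.0084,4.54e6,1.66e7
rho_CH3_M3,1101,1097,7,9.73e-10,0.0026,0.0164,2.67e6,1.69e7
nu_rings,1308,1313,6,2.13e-9,0.0026,0.0120,1.22e6,5.63e6
nu_i-ring_2,1360,1362,4,3.71e-9,0.0011,0.0383,2.96e5,1.03e7
nu_i-ring_1,1396,1394,4,4.15e-9,0.0034,0.0074,8.19e5,1.78e6
delta_C8-H,1455/1469,1469,7,1.38e-9,0.0014,0.0110,1.01e6,7.97e6
delta_CM,1517/1538,1536,10,1.58e-9,0.0013,0.0104,8.23e5,6.58e6
nu_C-C,1583,1583,4,5.90e-10,0.0002,0.0140,3.39e5,2.37e7
nu_C=C+C=N,1618,1624,6,2.12e-9,0.0003,0.0265,1.42e5,1.25e7
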