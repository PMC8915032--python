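id,kind,volume_l_per_day,cod_mg_l,cn_ratio,alk_mg_l,tox_mg_l,dist_R1_km,dist_R2_km,dist_R3_km
W1,sludge,27600,19900,17.8,4300,1.55,5.3,20.5,9.5
W2,sludge,47000,16900,20.6,3200,1.36,35.9,33.9,45.7
W3,sludge,46300,18600,19.4,10100,1.42,21.8,16.6,28.9
W4,sludge,20200,23400,15.6,3400,1.38,30.4,43.2,19.7
W5,sludge,38400,21100,17.9,4500,1.35,19.7,24.7,12.4
W6,sludge,34400,18800,14.0,3800,1.61,14.8,19.9,15.9
W7,sludge,13800,22600,15.3,2700,1.57,32.1,44.9,18.4
W8,sludge,4400,22100,15.2,1800,2.30,26.5,31.6,27.7
W9,sludge,10800,21700,15.1,5300,0.93,20.3,33.1,8.8
W10,sludge,9500,20400,15.5,2500,1.28,30,24.8,37.1
W11,sludge,17000,23300,14.8,7800,0.98,36.9,31.7,44
W12,sludge,6500,20100,16.5,3100,1.40,20.5,33.3,8.7
C1,industrial,9000,667400,42.5,250,0.01,15.9,11.1,23
C2,industrial,9000,497400,461.8,330,0.01,7,12,17.9
C3,industrial,9000,155900,3118.1,60,0.02,27.9,40.7,17.2
C4,industrial,9000,459100,274.1,660,0.10,16.2,11.1,22.9
C5,industrial,9000,657200,2330.6,630,0.01,52.8,65.6,43.8
C6,industrial,9000,266200,2832.4,20,0.01,56.1,33,21
C7,industrial,9000,262100,32768.4,110,0.01,36.7,24.1,66.4
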