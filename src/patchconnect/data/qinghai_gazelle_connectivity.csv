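pair_a,pair_b,euclidean_km,lcp_length_km,movement_cost,corridor_1km_cost,fst,fst_se,fst_significant,first_generation_migrants
GZ,HG,0.2,0.2,291,600,0.018,0.024,,1
TL,P1,2.5,2.9,3198,3800,,,,
HG,P1,3.6,4.5,6778,7500,,,,
SG,KM,6.2,7.7,9541,10100,,,,
KT,SI,7.2,8.2,10398,11000,0.102,0.122,,1
HD,KT,8.6,10.1,11558,12500,0.000,0.008,,2
HG,TL,7.0,9.2,12039,12500,,,,
HD,YZ,8.2,10.9,13137,13700,0.115,0.028,*,0
GZ,TL,7.6,9.6,13811,14400,,,,
WY,RQ,16.7,18.5,18733,19000,,,,
TL,P2,11.6,12.9,19145,20200,,,,
GZ,P2,14.6,16.7,26945,27500,,,,
SI,GZ,22.8,24.9,28468,29300,0.138,0.072,,0
SI,P2,17.4,23.1,36116,37000,,,,
KT,P2,19.4,26.8,42268,45000,,,,
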