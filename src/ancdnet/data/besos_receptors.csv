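id,max_volume_l_per_day,cod_mg_l,cn_ratio,alk_mg_l,tox_mg_l
R1,122000,18600,19.1,3100,1.41
R2,146000,19100,20.3,2900,1.68
R3,111000,18200,18.4,3400,1.53
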