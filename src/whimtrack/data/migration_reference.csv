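population,season,n_individuals,n_seasons,distance_km,distance_se,duration_d,duration_se,speed_kmd,speed_se
mackenzie_delta,autumn,12,21,11332,333.8,64,3.6,186,10.5
mackenzie_delta,spring,9,16,11518,487.7,55,2.1,216,12.1
hudson_bay,autumn,5,9,8989,236.3,68,9.0,145,11.7
hudson_bay,spring,6,9,8581,389.2,47,3.5,191,19.5
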