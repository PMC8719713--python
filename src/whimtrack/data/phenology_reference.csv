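population,season,n_individuals,n_seasons,mean_date,se_d
mackenzie_delta,breeding,10,18,31 May,2.5
mackenzie_delta,autumn_migration,13,26,7 July,2.0
mackenzie_delta,winter,13,25,30 August,3.3
mackenzie_delta,spring_migration,13,21,6 April,1.6
hudson_bay,breeding,15,21,3 June,4.24
hudson_bay,autumn_migration,11,17,22 July,3.0
hudson_bay,winter,9,15,18 September,4.1
hudson_bay,spring_migration,7,10,20 April,2.8
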