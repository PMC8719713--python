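season,mean_kmd,se,n_seasons
spring,206.9,10.47,25
autumn,173.8,8.79,30
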