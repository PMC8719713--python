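# Hudson Bay breeding population: shorter, more direct migration with the
# same autumn and spring corridor.  Same field conventions as the Mackenzie
# Delta preset.  Stopover stay means are capped near 1.5 d so that the
# published seasonal spans remain achievable (the published staging stays
# plus storm-driven stopover durations would not fit the autumn span).
name: hudson_bay
breeding_centroid: [57.5, -92.2]
winter_centroid: [6.1, -57.2]
mean_dates:
  breeding_arrival: 154    # 3 June
  autumn_departure: 203    # 22 July
  winter_arrival: 261      # 18 September
  spring_departure: 110    # 20 April
date_se_d:
  breeding_arrival: 4.24
  autumn_departure: 3.0
  winter_arrival: 4.1
  spring_departure: 2.8
date_n_seasons:
  breeding_arrival: 21
  autumn_departure: 17
  winter_arrival: 15
  spring_departure: 10
autumn_itinerary:
  - name: Hudson Bay
    lat: 55.5
    lon: -85.0
    mean_stay_d: 15.5
    se_stay_d: 3.66
    n_stays: 7
    post_stopover_rate: 1.8
    post_stopover_stay_d: 1.5
  - name: South Atlantic
    lat: 31.9
    lon: -81.1
    mean_stay_d: 28.4
    se_stay_d: 1.79
    n_stays: 13
    post_stopover_rate: 1.0
    post_stopover_stay_d: 1.5
spring_itinerary:
  - name: South Atlantic
    lat: 31.9
    lon: -81.1
    mean_stay_d: 29.2
    se_stay_d: 3.96
    n_stays: 10
    post_stopover_rate: 1.2
    post_stopover_stay_d: 1.9
autumn_waypoints:
  - []                                           # breeding -> Hudson Bay staging
  - [[49.3, -63.5], [38.0, -66.8]]               # offshore Atlantic corridor
  - [[24.5, -62.5], [13.0, -57.5]]               # across the Caribbean basin
spring_waypoints:
  - [[7.5, -73.5], [14.0, -81.5], [24.0, -80.5]]     # winter -> South Atlantic
  - [[37.4, -75.9], [42.0, -81.5], [45.5, -88.5], [50.5, -93.5]]  # over the Great Lakes
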