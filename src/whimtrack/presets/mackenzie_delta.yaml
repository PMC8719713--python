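# Mackenzie Delta breeding population: western loop migration.
# Dates are day-of-year means with printed SE and the number of tracked
# seasons they were computed over (SE * sqrt(n) = between-individual SD).
# Itinerary stays and post-staging stopover rates follow the published
# seasonal summaries; leg waypoints shape the route so each season's
# great-circle itinerary length matches the reported migration distances.
name: mackenzie_delta
breeding_centroid: [69.372, -134.894]
winter_centroid: [5.9, -55.2]
mean_dates:
  breeding_arrival: 151    # 31 May
  autumn_departure: 188    # 7 Jul
  winter_arrival: 242      # 30 Aug
  spring_departure: 96     # 6 Apr
date_se_d:
  breeding_arrival: 2.5
  autumn_departure: 2.0
  winter_arrival: 3.3
  spring_departure: 1.6
date_n_seasons:
  breeding_arrival: 18
  autumn_departure: 26
  winter_arrival: 25
  spring_departure: 21
autumn_itinerary:
  - name: Beaufort Sea
    lat: 69.7
    lon: -132.5
    mean_stay_d: 7.6
    se_stay_d: 1.25
    n_stays: 17
    post_stopover_rate: 1.3
    post_stopover_stay_d: 1.8
  - name: Hudson Bay
    lat: 58.5
    lon: -93.0
    mean_stay_d: 18.0
    se_stay_d: 2.58
    n_stays: 16
    post_stopover_rate: 0.1
    post_stopover_stay_d: 0.6
  - name: Atlantic Canada
    lat: 45.9
    lon: -64.2
    mean_stay_d: 19.3
    se_stay_d: 2.52
    n_stays: 19
    post_stopover_rate: 0.0
    post_stopover_stay_d: 0.0
spring_itinerary:
  - name: Gulf Coast
    lat: 29.3
    lon: -94.7
    mean_stay_d: 25.0
    se_stay_d: 2.51
    n_stays: 16
    post_stopover_rate: 2.4
    post_stopover_stay_d: 2.5
autumn_waypoints:
  - []                                           # breeding -> Beaufort Sea
  - [[73.0, -116.0], [69.0, -96.0], [62.0, -91.0]]   # Beaufort -> Hudson Bay
  - [[51.0, -79.0], [46.5, -70.5]]               # Hudson Bay -> Atlantic Canada
  - [[40.5, -43.5], [22.0, -44.0]]               # transoceanic to winter grounds
spring_waypoints:
  - [[7.5, -80.0], [13.0, -88.0], [21.0, -93.5]]     # winter -> Gulf Coast
  - [[33.0, -98.0], [38.5, -108.0], [44.0, -111.0], [50.0, -121.0], [56.0, -122.5], [63.0, -132.0]]
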