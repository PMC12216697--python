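- name: road_major_len
  source: roads
  statistic: length_sum
  layer_filter: major
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: road_secondary_tertiary_len
  source: roads
  statistic: length_sum
  layer_filter: secondary_tertiary
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: road_minor_len
  source: roads
  statistic: length_sum
  layer_filter: minor
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: road_all_len
  source: roads
  statistic: length_sum
  layer_filter: all
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: bus_station_n
  source: pois
  statistic: count
  layer_filter: bus_station
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: activity_n
  source: pois
  statistic: count
  layer_filter: human_activity
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: school_n
  source: pois
  statistic: count
  layer_filter: school
  radii:
  - 50
  - 100
  - 200
  - 500
  period: day
- name: market_n
  source: pois
  statistic: count
  layer_filter: market
  radii:
  - 50
  - 100
  - 200
  - 500
  period: day
- name: bar_n
  source: pois
  statistic: count
  layer_filter: bar
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: ndvi_mean
  source: ndvi
  statistic: raster_mean
  layer_filter: null
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: pop_mean
  source: pop_density
  statistic: raster_mean
  layer_filter: null
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: lc_formal_residential_share
  source: land_cover
  statistic: composition_share
  layer_filter: formal_residential
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: lc_informal_residential_share
  source: land_cover
  statistic: composition_share
  layer_filter: informal_residential
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: lc_cbi_share
  source: land_cover
  statistic: composition_share
  layer_filter: cbi
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: lc_other_share
  source: land_cover
  statistic: composition_share
  layer_filter: other
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: building_n
  source: buildings
  statistic: count
  layer_filter: null
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: waterway_len
  source: waterways
  statistic: length_sum
  layer_filter: null
  radii:
  - 50
  - 100
  - 200
  - 500
  period: both
- name: elevation
  source: elevation
  statistic: point_value
  layer_filter: null
  radii: []
  period: both
- name: dist_major_road
  source: roads
  statistic: distance_nearest
  layer_filter: major
  radii: []
  period: both
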