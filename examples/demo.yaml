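# Demo configuration: a 5 km synthetic city with a campaign of
# 9 fixed (45-day) and 120 rotating (7-day) monitoring sites.
seed: 7
out_dir: runs/demo

city:
  extent_m: [5000, 5000]
  cell_size_m: 50
  n_fixed_sites: 9
  n_rotating_sites: 120
  core_fraction: 0.5
  campaign_days_fixed: 45
  campaign_days_rotating: 7

prevalence:
  subsample_fixed_days: 30
  min_clip_fraction: 0.5
  collapse: site_date

lur:
  n_trees: 500
  cv_folds: 10
  n_permutations: 10
  radii: [50, 100, 200, 500]
  categories:
    - road_transport
    - animal_insect
    - music
    - speech
    - geophysical_nature

mask:
  road_predicate: intersects
  road_distance_m: 0.0

index:
  weights: [0.5, 0.5]
  normalize_jointly: false
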