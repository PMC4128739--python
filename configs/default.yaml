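# Default two-plot experiment configuration.
# Plots: "natural" = clumped reserve (~4858 ha), "managed" = interspersed
# farmland (~2061 ha); compositions give 60.9 % vs 74.1 % usable habitat.
landscapes:
  natural:
    dims: [700, 694]
    cell_size_m: 10.0
    composition: {0: 0.391, 1: 0.475, 2: 0.114, 3: 0.020}
    config: clumped
    patch_scale_m: 600.0
  managed:
    dims: [454, 454]
    cell_size_m: 10.0
    composition: {0: 0.259, 1: 0.140, 2: 0.543, 3: 0.058}
    config: interspersed
    patch_scale_m: {0: 100.0, 1: 450.0, 3: 100.0}

n_individuals: {natural: 4, managed: 6}
fixes_per_individual: [55, 64]
road_forage_share: 0.31
accuracy_sd_m: 35.0
sighted_accuracy_sd_m: 2.0
home_radius_m: 1500.0

n_nests: 60
min_dist_m: 50.0

h_m: 200.0
grid_resolution_m: 25.0
isopleth: 0.95

bootstrap_B: 10000
block_size_m: 100.0

abundance_n_weeks: 74
abundance_rate: {natural: 1.1, managed: 1.45}
abundance_dispersion: 3.0
abundance_transect_km: 10.0

seed: 2011
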