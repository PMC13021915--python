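# Example run configuration for `perilesion run --config run_config.toml`.
# A scaled-down cohort; omit [design] for the full 1000x1000 um default.

seed = 4
radii = [50.0, 100.0]
min_count = 10

[design]
width_um = 500.0
height_um = 500.0
pixel_size = 2.0
band_depth_um = 150.0
n_vessels = 2
vessel_radius_um = 30.0
total_density = 3e-3
rois_min = 2
rois_max = 3

[transform]
lower_pct = 0.1
upper_pct = 99.5
cofactor = 5.0

# Planted group differences (Control value, ONJ value)
[effects]
type_proportions = { Treg = [0.02, 0.06] }
functional_positivity = { Ki67 = [0.15, 0.30], pNFkB = [0.10, 0.25] }
density_factor = [1.0, 1.25]
thomas_types = ["Treg"]
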