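# Default simulation parameters (calibrated; see docs/methods.md).
# Flat key = value; units are part of the key name.
n_cells = 50
leader_fraction = 0.0
n_frames = 97
frame_interval_min = 15.0
fiber_axis = y
base_speed_follower_um_h = 8.0
base_speed_leader_um_h = 26.0
anisotropy_kappa = 4.0
leader_anisotropy_kappa = 0.3
persistence = 0.5
leader_persistence = 0.5
adhesion_strength_follower_per_h = 0.15
adhesion_strength_leader_per_h = 0.03
adhesion_radius_um = 25.0
adhesion_rest_length_um = 15.0
coupling_radius_um = 25.0
crowding_radius_um = 50.0
coupling_alpha_um_h = 40.0
crowding_beta = 1.0
heading_coupling = 2.0
speed_gain = 0.5
spacing_um = 15.0
cell_radius_um = 10.0
pixel_size_um = 2.0
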