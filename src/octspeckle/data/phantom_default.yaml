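# Default phantom: PTFE-like micro-tube (305 um lumen / 762 um outer wall)
# and a 400 um transparent rod embedded in an attenuating Intralipid-like
# background, with an air gap above the surface and a deep low-SNR noise
# band.  Voxel pitch 7.5 x 7.5 x 3.75 um (depth, fast, slow); 24 repeat
# frames per slow position.  Intensities are linear amplitude, arbitrary
# units.  Region speckle parameters are calibrated so that pooled 8640-pixel
# ROI histograms reproduce the characteristic Rayleigh goodness-of-fit
# ladder of the six materials (air/noise ~0.993-0.994, dyed water ~0.988,
# transparent solid ~0.983, semi-transparent solid ~0.96, Intralipid <0.93).
volume_shape: [150, 200, 32, 24]   # (depth, fast, slow, repeat)
voxel_pitch_um: [7.5, 7.5, 3.75]
surface_depth_um: 112.5
noise_floor_depth_um: 975.0
tube:
  center_depth_um: 535.0
  center_fast_um: 500.0
  inner_diameter_um: 305.0
  outer_diameter_um: 762.0
rod:
  center_depth_um: 400.0
  center_fast_um: 1100.0
  diameter_um: 400.0
seed: 0
regions:
  air:
    base_scale: 0.9
    shift: -0.22
    rayleigh_purity: 1.0
    decorrelation: 1.0
  noise:
    base_scale: 1.1
    shift: -0.20
    rayleigh_purity: 1.0
    decorrelation: 1.0
  dyed_water:
    base_scale: 1.4
    shift: -0.22
    rayleigh_purity: 0.6
    contamination_grade: 0.6
    decorrelation: 1.0
  transparent_solid:
    base_scale: 1.8
    shift: -0.26
    rayleigh_purity: 0.5
    contamination_grade: 0.8
    decorrelation: 0.9
  semi_transparent_solid:
    base_scale: 3.0
    shift: -0.21
    noise_floor_scale: 0.81
    decorrelation: 0.6
  intralipid:
    base_scale: 8.0
    shift: -7.5
    rayleigh_purity: 0.85
    contamination_grade: 0.6
    noise_floor_scale: 6.8
    depth_attenuation: 0.0008
    decorrelation: 0.75
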