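{
  "name": "deep",
  "description": "Full-scale spherical head with a deep (near-center) tumor, same skull window and arrays as the superficial fixture.",
  "phantom": {
    "scalp_radius": 92.0,
    "skull_radius": 85.0,
    "csf_radius": 78.0,
    "gm_radius": 75.0,
    "wm_radius": 60.0,
    "spacing": 2.0,
    "tumor_center": [
      15.0,
      0.0,
      0.0
    ],
    "tumor_core_radius": 12.0,
    "tumor_shell_thickness": 6.0,
    "defect_diameter": 20.0,
    "defect_axis": [
      1.0,
      0.0,
      0.0
    ],
    "montage": "LR",
    "transducer_pitch_mm": 30.0
  },
  "solver": {
    "applied_voltage": 60.0
  }
}
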