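# 50 MHz 25x25 phased array, lipid sphere in water, four-focus trapping layout.
array:
  n_elements_x: 25
  n_elements_y: 25
  pitch_um: 27.0
  kerf_um: 5.0
  center_frequency_mhz: 50.0
medium:
  density_kg_m3: 1000.0
  sound_speed_m_s: 1500.0
  shear_viscosity_pa_s: 8.9e-4
  dynamic_viscosity_pa_s: 8.9e-4
  impedance_mrayl: 1.5
particle:
  diameter_um: 240.0
  density_kg_m3: 950.0
  sound_speed_m_s: 1450.0
  impedance_mrayl: 1.4
focal_points:
  points_mm:
    - [0.18, -0.18, 0.67]
    - [-0.18, 0.18, 0.67]
    - [-0.18, -0.18, 0.67]
    - [0.18, 0.18, 0.67]
  target_pressures:
    - [1.0, 0.0]
    - [1.0, 0.0]
    - [1.0, 0.0]
    - [1.0, 0.0]
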