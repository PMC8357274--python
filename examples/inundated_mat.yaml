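layer_boundaries_mm:
- 0.0
- 1.0
- 2.0
- 3.2
- 4.5
- 6.0
true_rates:
  O2_light:
  - -0.000155
  - 0.000311
  - 0.00015
  - -0.00015
  - 0.0
  O2_dark:
  - -0.00012
  - -2.0e-05
  - 0.0
  - 0.0
  - 0.0
  Stot_light:
  - 0.0
  - 0.0
  - -2.0e-06
  - -1.0e-06
  - 2.0e-06
diffusivity:
  O2: 1.5e-09
  Stot: 9.6e-10
boundary_conditions:
  O2_light:
  - 0.25
  - zero_flux
  O2_dark:
  - 0.25
  - zero_flux
  Stot_light:
  - 0.0
  - 0.4
porosity: 0.35
correction: linear
pigment_bands:
- name: chlorophyll_a_upper
  center_wavelength_nm: 674.0
  bandwidth_sigma_nm: 10.0
  peak_attenuation_per_mm: 0.6
  depth_center_mm: 1.3
  depth_sigma_mm: 0.4
- name: chlorophyll_a_lower
  center_wavelength_nm: 674.0
  bandwidth_sigma_nm: 10.0
  peak_attenuation_per_mm: 0.8
  depth_center_mm: 2.3
  depth_sigma_mm: 0.4
- name: phycocyanin
  center_wavelength_nm: 624.0
  bandwidth_sigma_nm: 12.0
  peak_attenuation_per_mm: 0.5
  depth_center_mm: 2.3
  depth_sigma_mm: 0.5
- name: bacteriochlorophyll_a_845
  center_wavelength_nm: 845.0
  bandwidth_sigma_nm: 15.0
  peak_attenuation_per_mm: 0.5
  depth_center_mm: 3.5
  depth_sigma_mm: 0.6
- name: bacteriochlorophyll_a_902
  center_wavelength_nm: 902.0
  bandwidth_sigma_nm: 15.0
  peak_attenuation_per_mm: 0.35
  depth_center_mm: 3.5
  depth_sigma_mm: 0.6
- name: bacteriochlorophyll_c
  center_wavelength_nm: 745.0
  bandwidth_sigma_nm: 12.0
  peak_attenuation_per_mm: 0.6
  depth_center_mm: 4.5
  depth_sigma_mm: 0.7
matrix_attenuation_per_mm:
- 1.05
- 1.29
- 1.43
- 1.24
- 1.15
salt_thickness_mm: 2.5
salt_attenuation_per_mm: 0.00402013434140058
noise_sd: {}
seed: 0
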