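# Per-metal shell parameters for the five most abundant metalloprotein ions.
# Distances in angstroms, angles in degrees.
#
#   initial_upper      atomic-radius-based first-pass shell cutoff
#   abundant_element   most abundant first-shell ligand element
#   abundant_mean/sd   bond-length mean / standard deviation for that element
#   carbon_mode        main mode of the fictional metal-carbon distance
#   elements           element whitelist (>5% occurrence, carbon excluded)
#   updated_upper      (abundant_mean + abundant_sd + carbon_mode) / 2
#   small_angle_cut    small-angle removal cutoff for CG combination search
#   rf_band            compressed/normal training band for the random forest
version: 1
shell_lower: 1.3
metals:
  Zn:
    atomic_radius_pm: 135
    initial_upper: 3.20
    abundant_element: S
    abundant_mean: 2.341
    abundant_sd: 0.152
    carbon_mode: 3.071
    elements: [S, O, N]
    updated_upper: 2.782
    small_angle_cut: 68
    rf_band: [60, 70]
  Mg:
    atomic_radius_pm: 150
    initial_upper: 3.35
    abundant_element: O
    abundant_mean: 2.350
    abundant_sd: 0.368
    carbon_mode: 3.067
    elements: [O, N]
    updated_upper: 2.892
    small_angle_cut: 65
    rf_band: [58, 68]
  Ca:
    atomic_radius_pm: 180
    initial_upper: 3.65
    abundant_element: O
    abundant_mean: 2.481
    abundant_sd: 0.271
    carbon_mode: 3.432
    elements: [O]
    updated_upper: 3.092
    small_angle_cut: 60
    rf_band: [55, 65]
  Fe:
    atomic_radius_pm: 140
    initial_upper: 3.25
    abundant_element: N
    abundant_mean: 2.063
    abundant_sd: 0.134
    carbon_mode: 3.081
    elements: [S, O, N]
    updated_upper: 2.639
    small_angle_cut: 68
    rf_band: [63, 73]
  Na:
    atomic_radius_pm: 180
    initial_upper: 3.65
    abundant_element: O
    abundant_mean: 2.697
    abundant_sd: 0.369
    carbon_mode: 3.568
    elements: [O]
    updated_upper: 3.317
    small_angle_cut: 60
    rf_band: [50, 65]
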