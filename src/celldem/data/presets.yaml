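# Particle-type parameter presets.
#
# `baseline` holds the complete per-species parameter set used unless an
# experiment says otherwise.  Each named preset lists only the fields it
# overrides; everything else falls back to the baseline.
#
# Units are explicit in the key names: _um (micrometres), _N (newtons),
# _N_per_m (N/m), _Pa (pascals), _kg_per_s (kg/s).

baseline:
  M:  {R_um: 0.15, F_a_N: 1.0e-10, delta_um: 2.0, k_a_N_per_m: 1.0e-8, E_Pa: 1.0e+7, nu: 0.5, beta_kg_per_s: 0.05}
  C:  {R_um: 0.25, F_a_N: 5.0e-11, delta_um: 2.0, k_a_N_per_m: 1.0e-8, E_Pa: 1.0e+3, nu: 0.5, beta_kg_per_s: 0.05}
  NM: {R_um: 0.15, F_a_N: 1.0e-10, delta_um: 2.0, k_a_N_per_m: 1.0e-8, E_Pa: 1.0e+7, nu: 0.5, beta_kg_per_s: 0.05}
  N:  {R_um: 0.25, F_a_N: 5.0e-11, delta_um: 2.0, k_a_N_per_m: 1.0e-8, E_Pa: 5.0e+3, nu: 0.5, beta_kg_per_s: 0.05}

presets:
  table2: {}

  # Isolated-nucleus calibration: three stiffness levels for the nucleus
  # particles (E applies to both N and NM).
  nucleus_1kPa:
    N:  {E_Pa: 1.0e+3, F_a_N: 5.0e-12, beta_kg_per_s: 0.003}
    NM: {E_Pa: 1.0e+3, k_a_N_per_m: 1.0e-8, beta_kg_per_s: 0.003}
  nucleus_5kPa:
    N:  {E_Pa: 5.0e+3, F_a_N: 5.0e-12, beta_kg_per_s: 0.003}
    NM: {E_Pa: 5.0e+3, k_a_N_per_m: 1.0e-8, beta_kg_per_s: 0.003}
  nucleus_30kPa:
    N:  {E_Pa: 3.0e+4, F_a_N: 2.5e-11, beta_kg_per_s: 0.01}
    NM: {E_Pa: 3.0e+4, k_a_N_per_m: 5.0e-8, beta_kg_per_s: 0.01}

  # Whole-cell calibration band: the fitted upper and lower limits for
  # spread and round cells (the soft/stiff suffixes are the two endpoints).
  spread_soft:
    M:  {E_Pa: 1.0e+3, F_a_N: 5.0e-11, k_a_N_per_m: 5.0e-9, beta_kg_per_s: 0.002}
    C:  {E_Pa: 1.0e+3, F_a_N: 2.5e-12, beta_kg_per_s: 0.002}
    NM: {E_Pa: 1.0e+3, k_a_N_per_m: 5.0e-9, beta_kg_per_s: 0.002}
    N:  {E_Pa: 1.0e+3, beta_kg_per_s: 0.002}
  spread_stiff:
    M:  {E_Pa: 2.25e+3, F_a_N: 1.0e-10, k_a_N_per_m: 1.0e-8, beta_kg_per_s: 0.003}
    C:  {E_Pa: 2.25e+3, F_a_N: 5.0e-12, beta_kg_per_s: 0.003}
    NM: {E_Pa: 2.5e+4, k_a_N_per_m: 1.0e-8, beta_kg_per_s: 0.003}
    N:  {E_Pa: 2.5e+4, beta_kg_per_s: 0.003}
  round_soft:
    M:  {E_Pa: 1.0e+2, F_a_N: 1.0e-11, k_a_N_per_m: 1.0e-9, beta_kg_per_s: 0.001}
    C:  {E_Pa: 1.0e+2, F_a_N: 5.0e-13, beta_kg_per_s: 0.001}
    NM: {E_Pa: 1.0e+3, k_a_N_per_m: 1.0e-9, beta_kg_per_s: 0.001}
    N:  {E_Pa: 1.0e+3, beta_kg_per_s: 0.001}
  round_stiff:
    M:  {E_Pa: 1.5e+3, F_a_N: 5.0e-11, k_a_N_per_m: 5.0e-9, beta_kg_per_s: 0.002}
    C:  {E_Pa: 1.5e+3, F_a_N: 2.5e-12, beta_kg_per_s: 0.002}
    NM: {E_Pa: 2.5e+4, k_a_N_per_m: 5.0e-9, beta_kg_per_s: 0.002}
    N:  {E_Pa: 2.5e+4, beta_kg_per_s: 0.002}
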