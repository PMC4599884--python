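# Named adhesion parameter sets for the published experiment conditions.
#
# k_a_bm / delta_bm characterise membrane-particle attraction to the basement
# membrane (integrin-type attachment); k_a_m / delta_m characterise
# membrane-membrane attraction (cadherin-type cell-cell adhesion, short range).

adhesion_presets:
  # Reference spread-cell condition used for single-cell spreading.
  spread_reference: {k_a_bm_N_per_m: 1.0e-11, delta_bm_um: 3.0}

  # Epithelial-layer shape sweep baseline (spring constants are swept).
  shape_sweep: {delta_bm_um: 2.0, delta_m_um: 0.2}

  # Layer wall-compression conditions.
  layer_control:   {k_a_bm_N_per_m: 1.0e-11, delta_bm_um: 0.3, k_a_m_N_per_m: 5.0e-10, delta_m_um: 0.2}
  layer_strong_bm: {k_a_bm_N_per_m: 1.0e-10, delta_bm_um: 0.4, k_a_m_N_per_m: 5.0e-10, delta_m_um: 0.2}
  layer_weak:      {k_a_bm_N_per_m: 1.0e-12, delta_bm_um: 0.2, k_a_m_N_per_m: 5.0e-12, delta_m_um: 0.1}
  layer_budding:   {k_a_bm_N_per_m: 5.0e-10, delta_bm_um: 0.2, k_a_m_N_per_m: 5.0e-11, delta_m_um: 0.1}
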