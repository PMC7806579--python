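# Default positive-mode annotation run: three adducts (ammonium, sodium,
# potassium), two neutral losses (ammonia, water), dimers and trimers,
# combinations of up to two deltas, absolute tolerance 10 mmu.
filter:
  abs_intensity_min: 500      # cps
  rel_intensity_min: 1        # percent of the base peak
  isotope_ratio_range: [1, 100]
  isotope_tolerance: 0.010    # Da
  monoisotopic_validation: true

annotation:
  polarity: positive
  deltas: [NH3_adduct, Na_adduct, K_adduct, H2O_loss, NH3_loss]
  multimers: [1, 2, 3]
  max_depth: 2
  tolerance_mmu: 10
  # per-delta stacking caps (metal/proton replacements scale with labile
  # protons; ammonium adduction and ammonia loss do not stack)
  max_mult:
    Na_adduct: 3
    K_adduct: 3
    Ca_adduct: 2
    NH3_adduct: 1
    H2O_loss: 2
    NH3_loss: 1

io:
  output_dir: "."
  graph_format: graphml

seed: 0
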