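# Default heterodimer calibration: subunit A synthesized in 1.5x excess
# over its partner, free monomers degraded 5x faster than the complex,
# tight association. Units: AU and 1/h; only ratios matter for folds.
s_a: 1.5
s_b: 1.0
n_a: 1.0
n_b: 1.0
d_free_a: 5.0
d_free_b: 5.0
d_complex: 1.0
k_on: 100.0
k_off: 0.0
tagged_copies_a: 1.0
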