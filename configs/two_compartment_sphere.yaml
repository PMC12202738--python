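# Quarter-scale two-compartment sphere experiment:
# simulate -> add noise -> predict with offset conductivity -> evaluate.
grid_shape: [32, 32, 32]
spacing_h: 5.0e-3          # m
frequency: 128.0e6         # Hz (3 T)

phantom:
  kind: two_compartment_sphere
  radius_mm: 75.0
  inner_radius_mm: 37.5
  inner_offset_mm: 18.75

noise: {}                  # defaults: SNR 50 (|B1+|) / 80 (T1w carrier)

# anomaly:                 # uncomment to inject an input-conductivity error
#   center_mm: [92.5, 77.5, 77.5]
#   diameter_mm: 65.0
#   sigma_offset: 0.6

convergence_limit_C: 1.0e-6
smoothing_std: 4.0
smoothing_kernel: 11
display_threshold: 0.1     # S/m
seed: 1
output_dir: b1eval_out
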