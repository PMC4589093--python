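# Standard one-inclusion experiment; every key is optional.
phantom: one_inclusion      # one_inclusion | two_inclusion | cylinder_3d
seed: 1
snr_db: 10.0                # null for noiseless data
recon:
  xi: 0.001                 # Tikhonov regularization
  delta: 0.02               # relative-residual termination threshold
  max_outer_iters: 12
  # beta_deg: 45.0          # default: half the source spacing
wavelet:
  family: haar
  level: 1
pca:
  energy_fraction: 0.95
solver:
  tol: 1.0e-8
  maxiter_factor: 10
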