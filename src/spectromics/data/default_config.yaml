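# Default analysis configuration.  Every value here mirrors the library
# defaults; load_config() merges user overrides over this file.
optics:
  g: 0.9                 # Henyey-Greenstein anisotropy (both layers)
  n: 1.4                 # tissue refractive index; ambient is 1.0
  quadrature_order: 16   # adding-doubling direction-cosine nodes
  dd_default: 20.0       # dermis thickness, mm (effectively semi-infinite)

preprocessing:
  sam_threshold_deg: 78.46   # tissue iff angle to tissue reference <= this
  sam_center: true           # mean-center spectra before the angle
  spatial_bin: 2
  ei_red_nm: [610, 700]
  ei_green_nm: [510, 580]

features:
  ng: 32        # gray levels for histogram / co-occurrence quantization
  delta: 1      # co-occurrence offset distance (infinity norm), pixels
  angles: [0, 45, 90, 135]

selection:
  k: 10         # features kept by MRMR
  bins: 4       # quantile bins of the mutual-information estimator

classification:
  n_folds: 4

fit_bounds:      # lower, upper, initial; lower == upper means fixed
  fm:    [0.0, 0.1, 0.01]
  fHb:   [0.0, 0.15, 0.01]
  fHbO2: [0.0, 0.15, 0.01]
  fbrub: [0.0, 5.0e-5, 0.0]
  fCO:   [0.0, 1.0e-4, 0.0]
  fCOO2: [0.0, 1.0e-4, 0.0]
  a:     [0.5, 5.0, 2.0]
  b:     [0.0, 3.0, 1.0]
  fRay:  [0.0, 1.0, 0.2]
  de:    [0.01, 0.15, 0.06]
  dd:    [20.0, 20.0, 20.0]
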