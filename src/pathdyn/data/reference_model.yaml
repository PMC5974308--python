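# Reference configuration for the limonene-pathway kinetic model.
#
# Units: concentrations in arbitrary units (order mM), time in hours.
# The constants are a documented surrogate for literature-derived values,
# chosen so that (a) the reference strain shows non-trivial 72 h dynamics
# (early acetyl-CoA transient, peak-then-decline intermediates) and (b)
# production control is concentrated in a few enzymes — the terpene synthase
# step is strongly rate-limiting, the upstream mevalonate steps carry excess
# capacity — mirroring the driver structure real engineered pathways show.
# Host central metabolism enters as a constant acetyl-CoA source plus a
# first-order drain.

kinetic_constants:
  acetyl_coa_supply: 1.0
  acetyl_coa_decay: 1.0
  AtoB_kcat: 0.6
  AtoB_km: 0.40
  HMGS_kcat: 2.0
  HMGS_km: 0.30
  HMGR_kcat: 1.8
  HMGR_km: 0.30
  MK_kcat: 2.0
  MK_km: 0.30
  PMK_kcat: 2.2
  PMK_km: 0.30
  PMD_kcat: 2.0
  PMD_km: 0.30
  Idi_kcat_f: 3.2
  Idi_km_f: 0.25
  Idi_kcat_r: 1.2
  Idi_km_r: 0.25
  GPPS_kcat: 3.6
  GPPS_km_ipp: 0.15
  GPPS_km_dmapp: 0.15
  LS_kcat: 0.05
  LS_km: 0.20

# Medium-producer-like expression profiles: p(t) = k_f*t/(k_m+t) + k_l
reference_hill:
  AtoB: {k_f: 1.0, k_m: 8.0, k_l: 0.05}
  HMGS: {k_f: 1.0, k_m: 8.0, k_l: 0.05}
  HMGR: {k_f: 1.0, k_m: 8.0, k_l: 0.05}
  MK:   {k_f: 1.0, k_m: 8.0, k_l: 0.05}
  PMK:  {k_f: 1.0, k_m: 8.0, k_l: 0.05}
  PMD:  {k_f: 1.0, k_m: 8.0, k_l: 0.05}
  Idi:  {k_f: 1.0, k_m: 8.0, k_l: 0.05}
  GPPS: {k_f: 1.0, k_m: 8.0, k_l: 0.05}
  LS:   {k_f: 1.0, k_m: 8.0, k_l: 0.05}

# Log-uniform pool-sampling ranges: amplitudes span one decade around the
# reference level, half-saturation times 4-16 h, leak levels well below the
# saturating amplitude.
sampling_ranges:
  AtoB: {k_f: [0.333, 3.0], k_m: [4.0, 16.0], k_l: [0.02, 0.2]}
  HMGS: {k_f: [0.333, 3.0], k_m: [4.0, 16.0], k_l: [0.02, 0.2]}
  HMGR: {k_f: [0.333, 3.0], k_m: [4.0, 16.0], k_l: [0.02, 0.2]}
  MK:   {k_f: [0.333, 3.0], k_m: [4.0, 16.0], k_l: [0.02, 0.2]}
  PMK:  {k_f: [0.333, 3.0], k_m: [4.0, 16.0], k_l: [0.02, 0.2]}
  PMD:  {k_f: [0.333, 3.0], k_m: [4.0, 16.0], k_l: [0.02, 0.2]}
  Idi:  {k_f: [0.333, 3.0], k_m: [4.0, 16.0], k_l: [0.02, 0.2]}
  GPPS: {k_f: [0.333, 3.0], k_m: [4.0, 16.0], k_l: [0.02, 0.2]}
  LS:   {k_f: [0.333, 3.0], k_m: [4.0, 16.0], k_l: [0.02, 0.2]}
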