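# Default model parameters and scenario geometry (data, not code).
#
# Parameters were fixed once by the calibration procedure: the intensity
# kinetics f(m) = p3 - p4 m exp(-p5 m/2) - p6 m must have three uniform
# roots (stable / unstable / stable) with the middle root near 0.3 times
# the saturation scale m_sat = p3/p6; p7 is sized so the diffusion
# length sqrt(p7/f'(m_mid)) is about 0.1 R; and p1 is sized so that the
# Lagrangian displacement of epiblast material over the default run
# matches the morphogenetic scale (mean ~0.4 R between streak initiation
# and full extension).  With the values below the kinetic roots are
# approximately 0.26 / 1.18 / 3.50 and m_sat = 3.57.
params:
  p0: 1.0       # active-ingression propensity
  p1: 0.5       # shear/bulk viscosity ratio
  p2: 1.0       # shear-rotation coupling (elongated fibres)
  p3: 1.0       # myosin recruitment
  p4: 6.0       # base dissociation
  p5: 4.0       # catch-bond tension sensitivity
  p6: 0.28      # linear saturation
  p7: 0.005     # tension-propagation diffusivity
  v_b: 0.05     # outward-normal boundary (epiboly) speed
  R: 1.0        # domain radius

grid:
  nr: 64
  ntheta: 128
  ap_angle_deg: 270.0   # posterior direction (bottom of image)

run:
  t_end: 6.0            # streak fully extended along the AP axis
  cfl: 0.8
  dt_max: 0.02
  output_every: 1.0
  refactor_every: 25    # diffusion-operator refactorization cadence (steps)
  streak_div_threshold: -1.0   # divergence level defining the streak region

# Scenario geometry (fractions of R, angles relative to the posterior
# direction, in degrees).  Feature kinds: arc / ring / point.
scenarios:
  wild_type:
    features:
      - {kind: arc, radius: 0.7, center_deg: 0.0, half_width_deg: 50.0,
         sigma: 0.08, amplitude: 0.8}
    phi_init: azimuthal
  twin:
    features:
      - {kind: arc, radius: 0.7, center_deg: -60.0, half_width_deg: 25.0,
         sigma: 0.08, amplitude: 0.8}
      - {kind: arc, radius: 0.7, center_deg: 60.0, half_width_deg: 25.0,
         sigma: 0.08, amplitude: 0.8}
    phi_init: azimuthal
  teleost:          # marginal-zone mesoderm ring (constricts as it internalizes)
    features:
      - {kind: ring, radius: 0.8, sigma: 0.08, amplitude: 0.8}
    phi_init: azimuthal
  reptilian:          # wild-type pattern, ingression blocked
    like: wild_type
    p0_override: 0.0
  amphibian:          # teleost pattern, ingression blocked
    like: teleost
    p0_override: 0.0
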