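# Methods

## Model

The embryonic epithelium is a thin, approximately planar, highly viscous
sheet; inertia is negligible, so the velocity field solves an instantaneous
force balance ∇·σ_T = 0 at every moment. The total stress is the sum of a
viscous part σ_V = −p**I** + 2**S**_s (S_s the deviatoric strain rate) and
the active cable stress σ_A = m(**B** − **I**/2), **B** = e(φ)e(φ)ᵀ.
Because ingressing cells leave the plane, the sheet is compressible; the
continuity law ∇·**v** = −p₁(2p + p₀m) ties the planar divergence to the
isotropic viscous stress and to myosin-driven apical contraction. Using it
to eliminate the pressure turns the momentum balance into the elliptic
system

2p₁Δ**v** + ∇(∇·**v**) + 2p₁(**B**∇m + m∇·**B**) + p₁(p₀−1)∇m = 0,

solved for **v** given (m, φ) at each step; the pressure is recovered
afterwards as p = −((∇·**v**)/p₁ + p₀m)/2. The orientation evolves like a
material fibre (advection, rotation by the vorticity, shear-induced
rotation weighted by p₂), and the intensity by
recruitment − catch-bond dissociation − saturation + along-cable diffusion.
The tension entering the catch bond is closed at the tissue scale as
T_c = m/2, so the dissociation rate per unit m is p₄e^(−p₅m/2): it drops
with tension, the feedback that converts a patterned initial condition into
a focused streak. The exponent sign is negative by this physical argument
(a positive sign — a slip bond — kills the instability); a
`catch_bond_sign` switch on `ModelParams` exposes the slip-bond variant for
sensitivity exploration only.

Boundary conditions: Dirichlet velocity v = v_b n̂ on the rim (epiboly;
tangential component zero — the well-posed choice for a second-order
elliptic system given only a normal-speed datum), zero flux for m and φ.

## Parameters

All parameters are dimensionless (length scale x_c, velocity scale u_c,
stress scale μu_c/x_c). Defaults live in `gastruflow/defaults.yaml` — they
are data, not code — and were fixed once by the following calibration, in
this order:

1. **Kinetics (p₃=1, p₄=6, p₅=4, p₆=0.28).** The uniform kinetics
   f(m) = p₃ − p₄me^(−p₅m/2) − p₆m must have three roots
   (stable/unstable/stable) with the middle root ≈ 0.3 of the saturation
   scale m_sat = p₃/p₆. The defaults give roots 0.260 / 1.178 / 3.503 with
   m_sat = 3.571 and f′(m_mid) = 0.491.
2. **Tension-propagation diffusivity (p₇ = 0.005)** sized so the diffusion
   length √(p₇/f′(m_mid)) ≈ 0.1R — streak widths of roughly a tenth of the
   embryo radius.
3. **Viscosity ratio (p₁ = 0.5)** sized so that the Lagrangian displacement
   of epiblast material over the default run matches the morphogenetic
   scale: mean displacement ≈ 0.4R between streak initiation and full
   extension. Larger p₁ makes the baseline contraction (below) strong
   enough that every scenario collapses toward the centre within the run;
   smaller p₁ fails to extend the streak at all.
4. **p₀ = 1** (ingression on), **p₂ = 1** (elongated fibres), **v_b = 0.05**
   (epiboly slow compared with peak interior speeds ≈ 0.15), **R = 1**.
5. **Run length t_end = 6** — the time at which the wild-type streak has
   fully extended along the AP axis with maximal contrast between streak
   ingression and far-field divergence. Two caveats are worth recording.
   The *localized* streak peak equilibrates near 70 % of the uniform upper
   root: along-cable diffusion flattens a solitary spike below the uniform
   saturation value, and the spike only approaches the upper root on much
   longer timescales (the 1D runs show this explicitly). And the middle
   root is itself unstable, so fronts of activation invade the quiescent
   background at speed ≈ 2√(p₇f′); past t ≈ 10 this invasion erodes the
   streak's divergence structure. t_end = 6 sits comfortably inside the
   window where the streak is mature and the background is still quiescent.

## Initial conditions (scenarios)

Every scenario starts from the *unstable* middle root of f plus Gaussian
features, with azimuthal cables φ₀ = θ + π/2 (the experimental HH1
configuration). Geometry defaults (in `defaults.yaml`): the wild-type
sickle is an arc at 0.7R spanning ±50° about the posterior with cross-arc
width σ = 0.08R and amplitude 0.8; twins use two arcs at ±60°; the teleost
ring sits at 0.8R. Reptilian and amphibian modes reuse the wild-type and
teleost patterns with p₀ = 0. Feature amplitudes put the seeded maxima
above the unstable root so the instability amplifies them; the baseline
itself is stationary under the kinetics.

One structural consequence of the azimuthal initial director deserves
emphasis: φ₀ has a +1 nematic defect at the disk centre, and a uniform-m
azimuthal director field carries hoop tension with ∇·**B** = −r̂/r. The
baseline therefore drives a gentle centreward flow with a logarithmically
deepening divergence at the origin. This is part of the model, not an
artifact: it supplies the inflow that carries the posterior sickle toward
the centre (streak extension), and in the ring scenarios it makes the
marginal ring constrict toward the centre over the run — as the
experimentally induced circular PS does. The backward-FTLE attractor of the
teleost mode is consequently a compact rotationally symmetric structure
around the centre rather than a circle at the seeding radius.

## Numerics

**Spatial discretization.** Cell-centred radii r_j = (j+½)Δr (no node at
r = 0), uniform angles, fields stored as Cartesian components so the polar
origin needs no tensor bookkeeping. All derivative operators are sparse
matrices built from second-order central differences; Cartesian derivatives
use the exact polar expansions. The across-origin neighbour of an innermost
node is the node at (r₀, θ+π) — Cartesian components are genuine scalars
under that identification. Dirichlet rim data enter through quadratic ghost
extrapolation, zero-flux through mirror ghosts. The manufactured-solution
test shows observed convergence order ≈ 2.0 for the coupled solve; the
boundary ghost row is locally first-order but does not degrade the global
order.

**Elliptic solve.** The joint (u, v) system (2·nr·nθ unknowns) is
factorized once per (grid, p₁) by sparse LU and reused every step; an
iterative GMRES fallback (rtol 1e−10) covers failed factorizations. Reports
carry the discrete residual; non-convergence warns but returns fields.

**Time stepping.** The velocity is quasi-static (re-solved each step).
Advection (first-order upwind, across-origin aware) and reaction advance
together by explicit SSP-RK2 (Heun) under a combined advective/kinetic CFL
bound. The along-cable diffusion of m advances by backward Euler: on a
polar grid the angular diffusion CFL at the innermost ring scales as
(r₀Δθ)² ≈ 10⁻⁷, which would force ~10⁶ explicit steps; the implicit step
removes the constraint at the cost of one sparse factorization, refreshed
every 25 steps as φ drifts (the operator is dissipative for any frozen φ,
so lagging is stable; the consistency error is O(dt·p₇·|φ̇|)). The overall
splitting is first order, verified by the dt-refinement test. Orientation
is integrated through the double-angle pair (cos 2φ, sin 2φ), renormalized
each step — advection and rotation without branch cuts, and no boundary
data where characteristics leave the domain (epiboly makes the rim
outflow).

**Anisotropic diffusion.** Δ_φ m = ∇·(eeᵀ∇m) is discretized in
conservative finite-volume form with face-averaged diffusion tensors and
zero-flux rim faces, so total intensity is conserved *exactly* by
construction (the divergence form is chosen over the directional second
derivative eᵀ(Hess m)e precisely for this conservation property; the two
differ by first-order terms in ∇φ). Mixed-derivative stencils can
undershoot slightly; m is clipped at 0 with a warning if the undershoot
exceeds 10⁻⁴.

**1D model.** The 1D reduction describes the dynamics perpendicular to the
AP axis with the cables lying *along* the 1D coordinate (the sickle
configuration), giving (2p₁+1)u_xx + p₁(p₀+1)m_x = 0 — solved in closed
form, u_x = −α(m − m̄) — and diffusion p₇m_xx. With cables perpendicular to
the 1D axis both the active coupling and the diffusion would vanish and no
focusing instability exists, so the along-axis orientation is the only
reduction consistent with the phenomenology the 1D model is meant to show.

**Dispersion measurement.** `perturbation_growth_rate` measures, rather
than assumes, the linear response: a tiny sinusoidal perturbation is
evolved by a spectral 1D integrator, the mode amplitude log-regressed
against time, and the amplitude auto-reduced if split-half rates disagree
(linearity check). For this model the flow coupling is quadratic in the
perturbation, so the measured rate matches f′(m*) − p₇k² to the regression
tolerance — a nontrivial cross-check of the kinetics and the 1D mechanics.

**Lagrangian analysis.** Trajectories integrate by fixed-step RK4 on
velocities interpolated linearly in time and bilinearly in space;
out-of-domain queries hold the nearest boundary value and are flagged, and
flagged points are excluded from ridge statistics. FTLE gradients use
auxiliary four-point stencils (default half a grid cell) rather than
differencing the trajectory grid — better ridge fidelity at negligible
cost. Ridges are cells above a quantile (default 0.95) that are local
maxima transverse to the ridge (sampled along the strongest-downward-
curvature direction of the local Hessian); an exactly constant FTLE field
yields empty masks by convention. Disk-grid velocities are resampled to
Cartesian grids through padded (r, θ) interpolation — linear for
trajectory work, cubic where second derivatives are taken (force
inference), since second differences of bilinearly interpolated data do
not converge.

**Force inference.** F_A = −(∇(∇·v) + 2p₁Δv), evaluated from
boxcar-smoothed velocities by central differences — the discrete transcript
of the statement that in Stokes flow the active force is minus the viscous
force, so it can be read off measured velocities alone. On a converged
model solution it reproduces the model's active term to ~1 % (interior,
48×96/97² resolution), and affine velocity fields give identically zero.

## What the synthetic scenarios do and do not show

The scenario generator reproduces the *study conditions*: idealized
geometric seeds (arcs, rings, points) on a uniform unstable baseline, a
perfectly circular domain, uniform parameters, noiseless initial data
(optional seeded noise is available but off by default). Real embryos have
irregular geometry, graded and asymmetric myosin patterns, measurement
noise in PIV, and 3D effects (tissue buckling in the amphibian mode is
intrinsically 3D; the model only predicts its planar compressive
precursor). Passing tests therefore demonstrate that the implementation
solves the stated equations correctly and that the model's qualitative
phenomenology (focusing instability, streak formation and extension,
ingression patterns, mode switching by p₀ and initial pattern) is
reproduced under clean conditions — not that the model quantitatively fits
any particular embryo.

## Known limitations

* The force-balance response to p₀ is structurally weak (p₀ enters the
  velocity equation only through p₁(p₀−1)∇m); the reptilian/wild-type
  ingression contrast at the default conditions is a few percent, while
  the streak-length contrast is large (~35 %).
* First-order upwind advection adds numerical diffusion ~|v|Δx/2, which at
  32×64 resolution is comparable to p₇; quantitative streak amplitudes need
  the 48×96 or 64×128 grids used in the tests.
* The ridge extractor is a quantile heuristic, not a variational LCS
  method; ridge masks depend mildly on the quantile and grid.
* Long runs (t ≳ 10 at default parameters) leave the physically meaningful
  window: activation fronts from the seeded structures invade the unstable
  background everywhere.
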