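# Methods

## The model

`cartifls` simulates unconfined creep of an articular-cartilage layer
compressed between a rigid impermeable platen and bone, with the goal
of extracting the interstitial fluid load support (IFLS) — the
fraction of the applied contact stress carried by pressurized
interstitial fluid — over the course of a tribology experiment.

The tissue is a biphasic (fluid-saturated porous) continuum whose
solid skeleton has two parts:

* a **nonfibrillar matrix** (the proteoglycan gel), modelled as a
  compressible Neo-Hookean solid carrying all compressive stress:
  `sigma_nf = (mu/J)(B - I) + (lambda/J) ln(J) I`, with `mu, lambda`
  derived from the matrix modulus `E_nf` and Poisson ratio `nu`;
* a **collagen-fibril network**, tension-only and viscoelastic, with
  linearly strain-dependent stiffening.  Each fibril direction carries
  an equilibrium stress `sigma_eq = E_f0 eps + E_feps eps^2 / 2`
  (tangent modulus `E_f0 + E_feps eps`) in parallel with one Maxwell
  branch whose overstress obeys
  `dq/dt = E_tan deps/dt - (E_tan/eta) q`, damping `eta` fixed.
  Fibril strain is the logarithmic strain of the material line
  element along the fibril; stress and overstress are identically
  zero whenever that strain is non-positive.

The fibril network is homogeneous: two *primary* directions parallel
to the articular surface (radial and circumferential) and seven
*secondary* directions approximating an isotropic background, with a
primary:secondary density ratio of 3 (configurable).  Weights are
normalized so the network's uniaxial tangent modulus along a primary
direction at zero strain equals `E_f0`, making the fitted moduli
independent of the direction-set bookkeeping.

Fluid flow is Darcian with deformation-dependent permeability.  From
the void-ratio form `k = k0 ((1+e)/(1+e0))^M` and incompressible
constituents (`1+e = J (1+e0)`) this reduces to `k = k0 J^M`.

Fixed tissue constants: `nu = 0.47`, `eta = 947 MPa s`, `e0 = 3.5`
(water fraction 78%).  The five identified parameters are
`E_nf, E_f0, E_feps` [MPa], `k0` [m^4/(N s)] and the permeability
exponent `M`.

Because the source formulation of this model family is not uniquely
pinned down by its published descriptions, two choices here are
explicit package decisions: the equilibrium/Maxwell stiffness split
of the fibrils is 1:1 (both branches use the same strain-dependent
tangent modulus), and the compressible Neo-Hookean variant above is
used for the matrix.  Both satisfy every stated property of the
model family (tension-only fibrils, linear strain stiffening, single
damping constant, strain-dependent permeability) and both are
independently testable against closed forms.

## Finite-element solver

Axisymmetric structured mesh of 4-node quadrilaterals with bilinear
displacement *and* bilinear pore pressure (the classic equal-order
pore-pressure element); 2x2 Gauss quadrature; total-Lagrangian
finite-strain kinematics (the fitted regimes reach 30-50% strain, so
small-strain theory is not an option; a `small_strain` mode exists
solely for oracle comparisons).  Time integration is backward Euler
on a geometrically growing step (default 0.01 s growing by 1.3 up to
100 s — creep spans five decades), with Newton iteration and
automatic step halving on non-convergence.

Equal-order u/p pairs are not inf-sup stable in the incompressible
(early-time) limit; a local pressure-projection term acting on the
pressure increment, scaled by `stab_alpha/(2G)` with `G` a
representative shear stiffness, suppresses the spurious modes.
Halving `stab_alpha` moves the IFLS history by less than 0.2% of the
applied stress (asserted in the tests).

Boundary conditions: bone interface fixed and impermeable; symmetry
axis radially fixed and impermeable; outer edge traction-free and
free-draining (p = 0); platen rigid, impermeable and frictionless —
implemented by tying all top-surface axial degrees of freedom to a
single platen degree of freedom, to which the load is applied as a
0.5-s linear force ramp followed by a constant hold.  No contact
algorithm is used (full contact from the start; the contact pressure
is the nominal load/area).

The element tangent is a forward-difference linearization of the
element residual with respect to its 12 degrees of freedom, batched
over all elements in one vectorized evaluation.  This differentiates
the viscoelastic update and the tension gate consistently without
hand-derived moduli; a modified-Newton scheme reuses the factorized
tangent across iterations and steps until convergence stalls.

Outputs: platen displacement, axial strain (displacement/thickness),
the average pore pressure POR, IFLS = POR/(applied stress), reaction
force, and the nodal pressure field.  POR defaults to the
area-weighted average over the platen contact surface; a volume
average is available (`por_mode="volume"`).  With the default healthy
parameters the surface average gives ~83% IFLS just after loading
(the volume average gives ~91%), and the surface definition is kept
as the default because immediately after loading the fluid should
carry nearly — but not more than — the applied stress at the contact.

## Verification oracle

The linear biphasic unconfined-compression creep problem (frictionless
impermeable platens, free-draining lateral surface, step load) has a
closed-form solution.  Deriving it via Laplace transform gives

    eps_hat(s) = -(sigma0/(mu s)) (H_A I0(x) - 2 mu I1(x)/x)
                                / (3 H_A I0(x) - 8 mu I1(x)/x),

`x = a sqrt(s/c)`, `c = k H_A`, whose pole series is a Bessel-series
creep curve with characteristic roots of
`J0(b) = [4(1-2nu)/(3(1-nu))] J1(b)/b`.  The transform reproduces
both limits exactly (`sigma0/E` drained, `sigma0/(3 mu)`
instantaneous), and the series agrees with an independent radial
finite-difference solve of the primal equations to better than 0.5%
at the resolutions used in the tests.  The FE solver, run with no
fibrils, constant permeability, a frictionless base and ~1% strain,
matches the series within 2% from 10 s to equilibrium on the coarse
15 x 10 mesh.

## Parameter identification

The objective is the (optionally log-time-weighted) RMS error between
the simulated platen displacement and `model_share` (default 50%) of
the measured pair displacement, on the experimental time grid.  The
measured target is first projected onto the monotone cone (isotonic
regression) — creep under constant load cannot recover, and unlike a
running maximum the projection is unbiased under symmetric noise.

Search: bounded Nelder-Mead from Latin-hypercube starts
(`E_nf` in [0.01, 5] MPa, `E_f0` in [0, 20] MPa, `E_feps` in
[0, 1000] MPa, `k0` in [1e-16, 1e-13] m^4/(N s) on a log scale,
`M` in [0, 15]), each start followed by a bounded trust-region
Gauss-Newton refinement of the displacement residual vector.  The
simplex alone cannot resolve the narrow valley traded off between
`E_f0` and `E_feps` within a reasonable simulation budget; the
Gauss-Newton stage converges from any simplex endpoint near the basin
in ~10 outer iterations.  Restart agreement (the fraction of starts
ending within 10% of the best parameters) is reported per fit as the
uniqueness check.  Optimization runs on a coarse mesh (15 x 10 or
smaller); solver failures inside the search are penalized, with tight
step budgets so hopeless parameter regions fail fast.

## Tribology pipeline

* **Lift-off exclusion**: intervals where the axial force stays below
  20% of the nominal load (90th-percentile estimate, or explicit) for
  at least 5 s are excised with a 2-s guard band; the first 15 s of a
  record (load application plus filter width) are excluded as well.
  Rejection if more than half of a record is excluded.
* **Filtering**: 10-s centered moving average applied to the torque
  after stitching across exclusions, so loaded and unloaded data are
  never mixed.
* **Friction**: `mu = (3/2) |tau| / (N r)` for a rotating circular
  contact; effective velocity `v_eff = omega (2/3) r`; Hersey number
  `H = v_eff eta_lub / L_w` with load per unit length
  `L_w = W/(2 r_eff)` — the convention that reproduces all four of
  the study's printed Hersey values within 2% (alternatives
  selectable).
* **Regressions**: ordinary least squares for `mu` vs IFLS
  (`mu = mu_IFLS IFLS + mu_0`) and strain vs IFLS, with standard
  errors and R^2; R^2 = 0 by convention for constant responses.  The
  `mu`-IFLS fit can be restricted to an IFLS band: the fitted lines
  extrapolate below zero friction at the highest IFLS, so ground-truth
  recovery against a clamped-at-zero generating law is evaluated on
  the band where the law is linear (below IFLS ~ 0.7).  Standard
  errors can be inflated by sqrt(window x rate) to account for the
  serial correlation the moving average introduces.
* **Stribeck surfaces**: per-velocity `mu`-IFLS regressions evaluated
  on an IFLS grid and interpolated linearly across log10(Hersey).
* **Statistics**: Kolmogorov-Smirnov normality screen,
  Kruskal-Wallis across groups (with the slowest velocity excluded
  from group comparisons, mirroring the study's exclusion rule),
  Friedman across velocities within samples (fully tied blocks report
  statistic 0), and Pearson correlations of `E_nf` with `mu_0` and
  `mu_IFLS`.

## Synthetic experiments

The generator emulates the study design: four groups
(healthy/degraded x saline/BSF), three specimen pairs per group, four
angular velocities (36-1080 deg/s; effective velocities 1.5-44 mm/s),
10-Hz logs over a 10,000-s session with 10-s lift-offs after each
rotation block (18/124/180/516 rotations per block at the four
velocities).  Displacement comes from the FE creep model (the pair
displacement is the modelled layer's displacement divided by
`model_share`); torque inverts the friction formula with a
ground-truth law `mu(IFLS)` so that the pipeline recovers the law
exactly when noise is zero; the force drops to near zero during
lift-offs.

Generating conditions: healthy parameter medians
`E_nf = 0.3 MPa, E_f0 = 2 MPa, E_feps = 100 MPa, k0 = 2e-15
m^4/(N s), M = 5` (typical bovine values for this model family);
degraded groups are threefold softer with threefold higher `k0`.
Friction-law medians per group and velocity follow the study's
regression table, with an extra quadratic IFLS term (+0.03) for the
degraded groups reproducing their stronger nonlinearity.  Noise:
2 um displacement, 2e-4 N m torque, 0.1 N force.  Within-group
dispersion is log-normal with sigma = 0.15 — a documented guess, as
the source reports only group contrasts.  All randomness derives from
a single seed through deterministic substreams; identical seeds give
bit-identical records.

What the generator does *not* emulate: rehydration mechanics during
lift-offs (the force gap is the only signature), torsion-induced
fluid flow, migrating contact areas, depth-dependent tissue
structure, and specimen-to-specimen structural variation beyond
thickness.  Passing the end-to-end tests therefore demonstrates that
the pipeline recovers the quantities the model generates — not that
the model captures every feature of the real experiment.

## Problem sizes and numerical defaults

Simulation-based tests and the acceptance script run the coarse
15 x 10 mesh (150 elements; the default production mesh is 60 x 40 =
2,400 elements, and doubling the coarse mesh changes the final strain
by under 1%).  Identification tests fit 5 parameters on a 10 x 6 mesh
against a 3,500-s target with 5 Latin-hypercube starts.  Newton
tolerance is 1e-6 on block-scaled residual norms; tangent
finite-difference steps are 1e-9 m and 1 Pa.

## Known limitations

* The strain-IFLS relation of the simulated healthy creep is linear
  to R^2 = 0.983, slightly below the near-perfect linearity the
  original experiments report (0.997); in the linear biphasic limit
  the relation is exactly linear, and the residual curvature here
  comes from the strain-stiffening and permeability nonlinearities at
  the default parameter medians.
* Backward Euler is first-order: halving the time step moves the
  displacement history by ~0.5% at the default stepping; the
  convergence tests use finer baselines.
* The equal-order element's post-processed boundary flux is O(h)
  accurate; the fluid-mass-conservation check is therefore asserted
  once the pressure boundary layer spans several elements.
* Lift-off rehydration is not modelled, so simulated IFLS histories
  between lift-offs are smoother than experimental ones.
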