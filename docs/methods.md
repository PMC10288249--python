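# Methods

## The model

A thin, linearly elastic, isotropic plate in plane stress is discretized
by a uniform `q x q` grid of material points with spacing `h` (mm) and
thickness `t` (mm). Four gridded fields describe its state: the
displacement components `u_x`, `u_y` (mm), Young's modulus `E` (MPa) and
Poisson's ratio `nu`. They are linked by small-strain kinematics

    eps_xx = du_x/dx,  eps_yy = du_y/dy,  gamma_xy = du_x/dy + du_y/dx,

the plane-stress constitutive relation

    sigma = E/(1 - nu^2) [[1, nu, 0], [nu, 1, 0], [0, 0, (1-nu)/2]] eps,

and static equilibrium `div(sigma) = 0`. Equilibrium is enforced
discretely: for every 3x3 subregion of material points, the net force in
each direction is a valid (no-padding) convolution of the stress
components with fixed signed 3x3 stencils — a row-difference stencil for
the direct stress and a column-difference stencil for the shear, scaled
by `h t`. The two resulting `(q-2) x (q-2)` maps of residual forces
vanish, to second order in `h`, exactly when the continuum equations
hold. Every kernel sums to zero, so any uniform stress state is exactly
balanced, and the convolution is linear in the stress.

Two coordinate networks represent the unknown fields: a displacement
network (swish activations by default) and an elasticity network (ReLU
by default), each a fully connected multilayer perceptron taking the
material point's position, normalized to `[-1, 1]^2`, and returning the
field values at that point. Outputs are de-normalized by per-output
affine scales; the Poisson's-ratio head is `0.5 * sigmoid` (hard bound
to the physically admissible open interval `(0, 0.5)`), and the modulus
head is by default a softplus positivity guard whose scale is calibrated
so a freshly initialized network starts near the mean-modulus constraint
target. A raw linear modulus head is available (`identity`) for uses
that require exact piecewise linearity of a ReLU network.

Training minimizes, by full-batch Adam over all `q^2` points, a weighted
sum of: the normalized mean absolute residual force (each subregion's
residual divided by the 3x3 moving sum of the predicted modulus, which
makes the term invariant under joint rescaling of stress and modulus);
boundary-displacement and boundary-traction MAEs (forward problems);
the absolute deviation of the summed predicted modulus from a target
(inverse/mixed problems — this removes the multiplicative
non-uniqueness of displacement-only inversion); and the absolute
deviation of the predicted displacement mean from a target (mixed
problems — this pins the additive constant left free because only
displacement derivatives enter the physics). Forward problems solve for
`(u_x, u_y)` given the elasticity field and boundary data; inverse
problems solve for `E` and/or `nu` given full displacement fields; mixed
problems solve for one displacement component plus one elastic constant
given the other (measured, axial) component. At most two fields may be
unknown — there are only two equilibrium conditions. Each loading case
owns its displacement network; all loadings share one elasticity
network (this is how multi-loading training improves identifiability).

Because no deep-learning framework is used, reverse-mode
differentiation through the pipeline is implemented directly: each
mechanics operation carries a hand-written adjoint (the
finite-difference and convolution operators are linear, the constitutive
relation has a closed-form vector-Jacobian product), and the network
backward pass is standard layer-wise backpropagation. All adjoints are
verified against numerical differentiation in the test suite. Runs are
deterministic given their seed (pure double-precision numpy, no threaded
nondeterminism).

## Tunable parameters

| parameter | default | notes |
| --- | --- | --- |
| learning rate | 0.005 (mixed), 0.002 (forward/inverse experiments) | Adam; constant (no schedules by design). The L1 losses give constant-magnitude per-point gradients near an optimum, so the final accuracy floor scales with the learning rate; 0.002 measurably sharpens forward/inverse solutions at desk scale. |
| Adam beta1/beta2 | 0.9 / 0.999 | standard |
| restarts / ensemble | 10 / 5 (protocol default); 1-3 at desk scale | restarts differ only in initialization seed; the fields of the best `ensemble_size` runs by final loss are averaged pointwise, with predicted displacement components re-centered to the mean-displacement target first. |
| network depth x width | 16 x 128 (protocol default); 4 x 48 in desk-scale experiments | the full-scale protocol targets 256^2 grids; the packaged experiments use 24-48 point grids where a 4 x 48 network already over-parameterizes the field. |
| epochs | per experiment (10k-30k at desk scale) | the full-scale protocol uses 200k-800k epochs; budgets here scale with grid and network size. |
| w_r | 1 | residual weight; always positive. |
| w_u, w_f | 1 | boundary-term weights (forward mode). |
| w_e, w_d | auto-balanced at epoch 0, then frozen | see below. |
| grid | q = 24-48, extent 10 mm, t = 1 mm | residual forces scale linearly in `t`; the normalized residual loss is independent of it. |
| loading | 1% average normal strain (uniaxial) or a half-sine of peak 1% of the extent (top compression) | the quasi-static elastography regime. |

### Constraint-weight balancing

The mean-modulus and mean-displacement constraints are absolute
deviations, so each contributes a per-point gradient of constant
magnitude `w/q^2` that never decays during training. If that constant
exceeds the per-point gradient that the residual term produces, it
dominates the denominator of Adam's per-parameter step normalization
and spatial recovery stalls (empirically: with value-matched weights the
modulus field freezes at its near-uniform initialization). The weights
`w_e` and `w_d` are therefore set once, at epoch 0, so that each
constraint's per-point gradient equals the rms per-point gradient of
the residual term at initialization, and then frozen. Because the
modulus head is calibrated to start at the constraint target, a weak
constraint suffices to hold the scale.

## The synthetic-data generator

No measured elastography data ships with the package; all inputs are
produced by two procedural phantom families plus a plane-stress FEM
solver:

* **Rose phantom** — the curve `r = sin(8 theta / 5)` (rational
  frequency, so its 16 petals overlap; the curve closes over
  `theta in [0, 10 pi)`). The local modulus is linear in the number of
  petals covering the point, pinned to `[E_min, E_max]` =
  `[0.1, 1.0] MPa` on the grid, with uniform `nu = 0.5`
  (incompressible idealization — finite in plane stress). The
  petal-count field has a `pi/8` rotational symmetry and its maximum
  (five overlaps) sits at the curve's origin.
* **Inclusion phantoms** — ellipses/discs with per-shape `E` and/or
  `nu` over a uniform background, later shapes overwriting earlier
  ones; edges may be blended over a tanh ramp of chosen width
  (`smooth`, mm). Smooth edges are the canonical choice for
  accuracy-sensitive experiments because the discrete equilibrium
  stencils are second-order consistent only where the stress is smooth:
  across a step discontinuity the residual at the *true* field is
  O(h), which at coarse grids exceeds the residual of smoother wrong
  fields and caps the attainable recovery accuracy (measured below).
* **FEM ground truth** — bilinear quadrilateral (Q4) elements on the
  same grid, 2x2 Gauss quadrature, element properties the average of
  the four corner nodal values, Dirichlet data imposed by elimination,
  direct sparse factorization. Boundary conditions: uniaxial stretch
  (grip two opposite edges; exact 1% mean normal strain by
  construction), or a half-sine axial compression of the top edge
  (transducer-like). The solver passes the linear patch test to machine
  precision and its reactions balance to solver tolerance.

What the generator does *not* emulate: ultrasound speckle, RF-signal
noise, displacement-tracking artifacts, anisotropy, nonlinearity, 3D
effects. Passing tests therefore demonstrate correctness of the method
on clean, grid-sampled, linearly elastic plane-stress data — not
robustness to measurement noise.

## Desk-scale study conditions and what they show

The full-scale protocol (256^2 grids, 16x128 networks, 200k epochs, 10
restarts) is far beyond a single-CPU numpy budget; the packaged
experiments run at `q = 20-48` with 4x48 networks and 6k-30k epochs.
Consequences, measured and documented rather than hidden:

* **Forward problems** converge well: the learned displacement matches
  the FEM solution to <1% relative L2 on a homogeneous plate (q = 33)
  and a few percent on a smooth-inclusion plate (restart averaging
  reduces the Adam jitter floor).
* **Inverse problems** recover smooth-edged modulus fields to a few
  percent MRE. Sharp (step-edge) inclusions floor at ~7-12% MRE
  depending on grid (the truth itself is not a discrete-residual
  minimizer at a step; see above).
* **Mixed problems** are the hardest at desk scale: with one measured
  displacement component, a uniform strain shift of the predicted
  component is penalized only where the modulus varies spatially, and
  coarse grids admit near-null solutions along that gauge. Desk-scale
  mixed runs therefore plateau at large modulus MRE, and the packaged
  mixed experiments are used for invariance and ranking assertions
  (plus an honestly reported scaled-down tracking number), not for
  absolute accuracy claims. Full-scale training resolves this regime.
* **Multi-loading (duo) training** sharply improves joint E + nu
  recovery (the x- and y-loadings constrain complementary regions —
  the "eggshell" shielding differs between them), replicating the
  full-scale ordering duo < single at desk scale (measured: modulus MRE
  drops from tens of percent under one loading to ~2% under two).
* **Restart variance.** On the inclusion forward problem individual
  restarts scatter widely and the final loss does not rank them (the
  lowest-loss restart can carry the largest field error — the discrete
  problem tolerates weakly-penalized smooth error modes), so forward
  experiments average all restarts pointwise instead of selecting by
  loss.
* **Activation orderings need depth.** The sigmoid elasticity
  network's failure is a vanishing-gradient effect: at depth 4 it
  trains fine, at depth 8+ (the full-scale protocol uses 16) it ranks
  clearly worst while the swish displacement network beats the ReLU
  one, matching the full-scale comparison. The packaged ranking
  experiment therefore uses depth-8 networks.

## Numerical choices

* Strain derivatives: second-order central differences in the
  interior, one-sided second-order stencils on the edges. A documented
  alternative would be to reuse the 3x3 subregion neighborhood; the
  2-point choice keeps strain local to rows/columns.
* Kernel orientation: array axis 0 is y increasing; the sign
  convention is pinned by the property "FEM stress fields produce
  near-zero residuals", which fails loudly if flipped.
* `nu = 0.5` is admitted as the incompressible idealization (plane
  stress remains finite there); inside the FEM constitutive matrix it
  is clamped to 0.4999 as a no-op guard.
* MRE normalizes by the number of summed points (`100/q^2` with a
  double sum), i.e. it is the mean of the pointwise relative errors; it
  requires strictly positive truth (zero Poisson's ratios are excluded
  from the phantoms for exactly this reason).
* Divergence (non-finite loss or an optimizer blow-up that drives a
  field out of its admissible range after epoch 0) aborts a run with
  its epoch index; diverged restarts are dropped from ensembles.
* Degenerate inputs (q < 3, nonpositive h/t/E, nu outside (0, 0.5],
  constraints that leave rigid-body modes, more than two unknown
  fields) are rejected with explicit errors.

## Known limitations

* 2D plane stress only; no plane strain or 3D.
* Clean synthetic data only (no noise model).
* Desk-scale mixed-mode accuracy is identifiability-limited (above);
  the invariance properties, not the MRE, are the reproducible
  desk-scale content of that mode.
* The L1 losses plus constant-rate Adam leave a jitter floor
  proportional to the learning rate; the restart-ensemble average is
  the protocol's mitigation. Learning-rate schedules are deliberately
  out of scope.
* No Fourier-feature or convolutional encoders (out of scope), which
  would otherwise accelerate the spectrally stiff displacement fits.
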