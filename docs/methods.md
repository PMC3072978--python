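# Methods

`simep` implements two steady-state models of singularity-induced
micro-electroporation: a configuration in which two coplanar electrodes,
separated by a nanometre-scale insulator, sit under an electrolyte.  The
electric field diverges at the electrode–insulator junctions, so fields
strong enough to permeabilize cell membranes (reversible electroporation at
~1–3 kV/cm, irreversible at ~10 kV/cm) can be generated with applied
voltages of a few volts.

## Primary current distribution model (channel)

The channel is a periodic sequence of anode–insulator–cathode units; one
period is modelled as a rectangle.  Only ohmic losses are considered, so the
electrode surfaces are equipotential and the potential Φ solves the Laplace
equation with Dirichlet data Φ=1 (anode) and Φ=0 (cathode) on the bottom
edge and zero normal flux on the insulator, the side walls (periodic
symmetry planes) and the top edge (the channel mid-plane).

Non-dimensionalisation: both coordinates are scaled by the active electrode
length l, which keeps the Laplace operator isotropic.  The geometry is then
fully described by two numbers — the aspect ratio G = h/l (half channel
height over electrode length; the top edge sits at y = G) and the relative
insulator thickness ε = d/l, the fraction of the unit-length bottom edge
occupied by the insulator.  ε = 0 is the idealised singular limit: anode and
cathode meet at a point, where the potential is discontinuous; the shared
node carries the mean of the two electrode potentials, and all reported
quantities are evaluated away from it.

The figure of merit is |E*| at the mid-plane point above the insulator
centre, (X, Y) = (0.5, 1) in the height-scaled convention (a node of every
grid by construction).  Dimensional fields follow as E = E* · V_d / l where
V_d is the electrode potential difference.  The orientation G = h/l (rather
than l/h) is fixed by the physics: shallower channels must concentrate the
field at the mid-plane, which this orientation reproduces — and it was
cross-checked against a closed-form separation-of-variables series for the
ε = 0 limit (|E*| at the probe = Σ_odd-n 2 / cosh(nπG)), which the solver
matches to better than 0.5%.

## Secondary current distribution model (kinetic cell)

The dimensional model (default domain 10 µm long, 20 µm high, 100 nm
insulator centred on the bottom edge) adds activation losses: at each
electrode node the normal current density entering the electrolyte must
equal the Butler–Volmer kinetic current

    i(η) = i0 · [exp(α_a F η / RT) − exp(−α_c F η / RT)],

with the surface overpotential η = φ_metal − φ_s − E_eq taken from the local
electrolyte potential φ_s.  The cathode metal is the ground, the anode metal
sits at V_app; the applied voltage then splits identically as
V_app = E_cell_eq + η_a − η_c + ΔΦ_ohm with E_cell_eq = E_eq,anode −
E_eq,cathode = 2.06 V for the packaged platinum/water couple.  Concentration
(mass-transfer) losses are outside the model by definition.

F = 96500 C/mol and R = 8.314 J/(mol K) are fixed at the values the model
parameters were stated with, not at CODATA precision; T defaults to 298 K.

### Packaged kinetics and the exchange-current unit trap

`platinum_water()` ships the water-electrolysis couple on platinum:
anode (oxygen evolution) i0 = 10⁻⁸ A/cm² = 10⁻⁴ A/m², cathode (hydrogen
evolution) i0 = 10 A/cm² = 10⁵ A/m², transfer coefficients 0.5, E_eq = 1.23
and −0.83 V.  Exchange current densities in the electrochemical reference
literature are tabulated in A/cm²; carrying such numerals into an SI solver
unconverted weakens the kinetics by four orders of magnitude and shifts
every polarization curve by ~0.5 V.  The packaged values are the SI
conversions; the fixture docstring quotes both unit systems, and every
kinetic parameter can be overridden through the config interface
(`i0_anode`, `i0_cathode`, `alpha_*`, `E_eq_*`, `T`).

### Nonlinear solution strategy

The kinetic boundary condition makes the problem nonlinear.  Each outer
iteration linearises i(φ_s) about the current boundary potential, imposing a
Robin condition (flux value plus slope·φ), and re-solves the linear problem
— i.e. a Newton iteration on the boundary nonlinearity, which converges
quadratically (typically 3–6 iterations per voltage).  Updates are damped by
step-halving if the boundary-current residual grows.  Voltages more than
0.1 V above the 2.06 V open-circuit point are reached by a continuation
ladder with steps ≤ 0.1 V, each rung seeded with the previous potential;
this tames the stiff exponential of the sluggish anode.  Convergence is
declared when the maximum nodal change of the boundary current density
drops below `outer_tol` (default 10⁻⁶) relative to the maximum density,
floored at the smallest exchange current density so that the open-circuit
state (all densities zero) terminates; a machine-precision fixed point of
the potential is also accepted.  A solve that converges while the ±500
overflow clip on the Butler–Volmer exponent is active raises an error
rather than returning silently; V_app at or below open circuit yields
I ≤ 0 and is flagged `no_drive`.

### Reported quantities

* Field: E = −∇φ by central differences (second-order one-sided at
  boundaries).  The headline readout is |E| at the insulator-centre surface
  node (x = L/2, y = 0) — the corner singularities sit at the insulator
  *edges*, so this value is mesh-convergent — plus the full centreline
  profile above the insulator.
* Current: nodal densities −σ ∂φ/∂n extracted by second-order one-sided
  differences and integrated by the trapezoid rule per segment; the total
  cell current uses the kinetic densities (exact in the discrete sense).
  Anode and cathode totals cancel within 1% on converged meshes.
* Power: P = V_app × I per unit device footprint (per-depth current divided
  by the domain length), reported in µW/cm².  The footprint is the only
  physically meaningful reference area for a 2D per-depth model; no hidden
  normalisation constant is applied (see Limitations).

## Discretisation

One finite-difference core serves both models: the standard 5-point stencil
with non-uniform-spacing coefficients, zero-flux edges by ghost-node
reflection, and every non-Dirichlet row scaled by its dual-cell area.  The
scaling symmetrises the operator and equilibrates the ~10⁹ dynamic range
the graded meshes otherwise produce, which is what previously limited the
attainable accuracy of the direct sparse factorisation (SuperLU).  The
relative residual of every solve is checked against 10⁻¹⁰.

Meshes are tensor grids graded toward the two electrode–insulator junctions
(and toward the bottom edge in y) by a power-law stretching map applied to
a uniform parameter grid; `grading` is the stretching exponent (1 =
uniform; defaults 2.0 primary / 2.5 secondary).  Because the map is
independent of the node count, doubling `n_base` produces *nested*
refinement — coarse nodes are a subset of fine nodes — which the
convergence machinery exploits.  A geometric-ratio grading was considered
and rejected: it cannot nest.  Each electrode and the vertical direction
get `n_base` intervals; the insulator gets 2·max(1, n_base//4), kept even
so a node always lies on the probe line x = L/2.

Mesh convergence is part of the API contract: the primary probe is reported
with a `converged` flag requiring < 1% movement between n_base and
2·n_base; the secondary centre field used in the reproduction scripts must
move < 2% between nested levels (48, 64).  Problem sizes used by the
shipped scripts — ~7.4·10⁴ nodes (primary, n_base = 96 after doubling) and
~10⁴ nodes (secondary, n_base = 64) — were chosen as the coarsest levels
that satisfy those criteria with margin.

## Verification

* Dense-oracle equivalence: on small grids the sparse solver matches an
  independently assembled dense solve of the same stencil equations to
  10⁻¹⁰, for Dirichlet and Robin/flux conditions.
* Second-order convergence on the manufactured harmonic solution
  sin(πx)·sinh(πy); discrete maximum principle on Dirichlet problems.
* The ε = 0 primary probe matches the analytic series (above).
* The 2D kinetic solver, run on a facing-electrode geometry where the
  problem degenerates to 1D, matches a closed-form scalar-root cell model
  (`solve_1d_cell`, bracketing root finder on the voltage budget) to
  ~10⁻¹²; the 1D model itself is validated against Tafel asymptotics.
* Conservation, voltage-budget closure, field/current consistency at the
  electrodes, and the qualitative trends (field decreasing in ε and in σ,
  current monotone in V_app, σ-insensitivity of the field at high voltage)
  are enforced by the property-test suite.

## Limitations and known discrepancies

* Both models are steady-state; double-layer charging, gas evolution,
  concentration gradients and the fluid flow that pulses cells through the
  channel are all outside scope.  Saline instead of water enters only
  through σ.
* The published reference values this package is checked against carry the
  unit ambiguities documented above.  With the A/cm² reading of the
  exchange currents, the package reproduces the published 413%/115%
  channel-model gains within 2–7% and the published 3.5 V insulator-centre
  fields within 9–22%; the 2.7 V fields sit 17–42% below the published
  numbers.  The residual gap is consistent with finite-element
  surface-field extraction on an unreported mesh near the 100 nm corner
  singularities, which overshoots; the values here are mesh-converged.
* The published absolute power-input values are mutually inconsistent with
  the published fields (they imply currents ~10⁴× smaller than the ohmic
  drops the fields require) and cannot be matched by any choice of
  reference area; only their σ-ordering and ratios are reproduced.  The
  package therefore reports the physical footprint-normalised power and
  does not bake in a fitted normalisation constant.
* The corner-singular field maximum (used in the worked channel example)
  grows without bound under refinement; it is reported at a stated mesh
  with the two singular junction nodes excluded, and only lower-bound
  claims are made of it.
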