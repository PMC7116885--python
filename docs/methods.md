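# Methods

## Scope and model overview

fibroclefts represents interstitial fibrosis in cardiac simplex meshes as
networks of no-flux clefts and simulates their electrophysiological
consequences.  The pipeline has four stages: (1) convert a per-element
image-intensity field into per-face fibrosis probabilities and sample
seeded network realizations; (2) split the mesh along the sampled faces
with a vertex-based local connectivity analysis so the resulting topology
is *tight* (no current leak across any cleft); (3) solve the monodomain
reaction–diffusion equation on the split mesh with finite elements and
human ventricular membrane kinetics; (4) drive arrhythmia-probing
protocols (ERP search, programmed stimulation, transmural activation
timing, the 2D transient-block test).

Units are mm / ms / mV / µA·cm⁻² / mS·cm⁻¹ throughout; the solver
converts lengths to cm internally so that `χ C_m M v̇ = −K v` balances in
µA with `χ = 1400 cm⁻¹` and `C_m = 1 µF/cm²`.

## Fibrosis probabilities and sampling

For every interior face whose two adjacent elements are tagged as
enhanced (LGE), the probability of being fibrotic is
`p = ρ_max · |cos θ| · I*` with `I*` the clamped normalized intensity and
`θ` the angle between the face normal and the local sheet normal.
Implementation choices where the formulation is open:

* **|cos θ|** — face normals carry a sign ambiguity; a face and its
  flipped normal are the same geometric cleft, so the magnitude is used.
* **Sampling rule** — a face is included when a uniform [0, 1) draw falls
  *below* its probability (standard Bernoulli).  This keeps the stated
  monotonicity — more enhancement, more fibrosis — and makes `ρ_max` the
  expected fraction at full intensity and alignment.
* **Per-face quantities** — `I*` is averaged over the two adjacent
  elements; the sheet normal is the normalized mean of the two adjacent
  triads' sheet normals (faces sit between elements; averaging is
  symmetric).
* **Seeds** — realization `r` of density index `d` uses
  `base_seed + 1000·d + r`, reproducible and collision-free at study
  scale.  The density sweep (0.1…1.0 step 0.1, 15 realizations, plus an
  empty control appended last) yields 151 networks.

Boundary faces never enter a network: a cleft on the tissue surface has
no interior to disconnect (attempting to split one warns and skips).

## Vertex splitting with local connectivity analysis

Vertices lying on at least one network face are visited in ascending
index order.  At each vertex a graph over the star elements is built from
the *current* (partially rewritten) connectivity; two elements are linked
when they share a face containing the vertex whose original-index key is
not in the network.  The element pairs that each network face must
disconnect are taken from the **original** adjacency, so a face whose
shared edge has already been unshared by a neighbouring vertex's split is
still enforced — skipping those was the one genuinely subtle bug found
during development, and it produced leaks at cleft ends.

If a pair remains connected, the local connectivity is cut along the
geometric continuation of the cleft: in 2D the single star edge whose
angle to the split edge is closest to 180°; in 3D candidate faces in
descending order of `|n_f · n_split|` (most parallel first) until the
pair separates.  Because face normals have no canonical sign, the
magnitude of the dot product with "most parallel first" is the
orientation-free reading of extending the cleavage plane, and it is the
3D analogue of the 2D collinearity rule.  Fallback cuts modify the local
graph only; they are never added to the physical no-flux set, so cleft
ends remain partially coupled (a crack tip), which is the intended
physics.  Ties between candidates are broken by face key; component 0
(which keeps the original vertex index) is the component containing the
lowest element index.  Each further component receives a fresh vertex
with identical coordinates, so geometry (total area/volume, coordinates)
is bit-identical before and after splitting, and re-splitting a split
mesh is a no-op.

The **leaky** assignment used by the 2D test case runs the same algorithm
but, at any vertex whose analysis yields four groups, merges diagonally
opposite groups (by angular order of group centroids around the vertex),
emulating naive per-edge node doubling without connectivity analysis.
Both topologies share the identical split-edge set.

**Isolated component removal** builds the element graph of the split mesh
and keeps the largest connected component (ties broken towards the lowest
element index, with a warning); unreferenced vertices are pruned and all
maps remapped.

**Tightness audit.**  Two order-independent conditions: (1) the elements
originally adjacent across every network face share no node of the split
mesh; (2) at every split vertex, element groups that are disconnected in
the original star once network links are removed reference disjoint sets
of vertex copies.  Fallback refinements (extra duplication at cleft ends)
are conservative and pass; the leaky assignment fails (2) exactly at its
merged vertices.  The audit recomputes its reference partition from the
original connectivity rather than trusting the splitter's bookkeeping.

## Membrane models

The default kinetics are the ten Tusscher–Panfilov 2006 human ventricular
model, epicardial parameter set (19 state variables), integrated with
Rush–Larsen updates for the twelve gating variables and forward Euler for
the potential, the calcium subsystem (with the analytic instantaneous-
buffering quadratic) and the concentrations, at `dt = 20 µs`.  The
epicardial variant is chosen because the modelled tissue carries no
epi/endocardial gradient and it is the common single-variant default.
The L-type calcium GHK-type flux has a removable singularity at
`V = 15 mV`, handled by its Taylor limit.  The quiescent state is the
published initial conditions relaxed by 10 s of stimulus-free integration
(cached per process); single-cell checks give a resting potential near
−86 mV, APD90 ≈ 300 ms at slow rate, refractoriness at a 150 ms coupling
interval and recovery at 450 ms — bracketing the ERP search range.

A two-variable Mitchell–Schaeffer model (`τ_in = 0.3`, `τ_out = 6`,
`τ_open = 100`, `τ_close = 120` ms, `u_gate = 0.13`, mapped to mV as
`V = −80 + 100u`) serves as a fast surrogate for protocol-level property
tests.  Its recovery constants are chosen so the surrogate remains
excitable at the protocol's shortest coupling interval (270 ms) while
retaining rate-dependent action-potential duration and conduction
slowing.  Both models are implemented as numba kernels over per-node
state arrays; acceptance-level quantities always use the ventricular
model.

## Monodomain solver

Piecewise-linear elements with a lumped mass matrix; the anisotropic
per-element tensor is `σ_t I + (σ_l − σ_t) f fᵀ` from the fibre direction
(transversely isotropic — the modelled conduction data distinguish only
fibre and cross-fibre velocities).  Pure Neumann assembly gives zero
stiffness row sums, which is precisely what makes unshared (split) faces
insulating.  Time integration is Godunov splitting with the PDE step
equal to the ionic step (20 µs): matching the steps avoids
splitting-order ambiguity.  The implicit-Euler diffusion system matrix is
constant and symmetric positive definite; it is factorized once (SuperLU)
by default, with a Jacobi-preconditioned conjugate-gradient option
(relative tolerance 1e-8, warm-started) that agrees with the direct solve
to well below physiological resolution.  Stimuli are transmembrane
currents of 500 µA/cm² for 2 ms in a 1 mm-radius ball (disc in 2D) unless
a mask is given; the radius is a package choice.  Activation is the first
upward 0 mV crossing, detected online at full solver resolution and
linearly interpolated between steps.

**Conduction-velocity tuning.**  Conductivity is calibrated per (target,
resolution, model): a planar wave is launched on a strand (12 mm
tetrahedral strand, or a 2D strip at the test-mesh resolution), velocity
is measured by regressing activation time on distance over the central
half, and the conductivity is iterated with the diffusion scaling law
`σ ← σ (CV_target/CV_measured)²` until within 1 % (quadratic-law
fixed-point, typically 3–5 simulations; propagation failure quadruples σ
and retries).  Results are cached in-process.  Enhanced-zone bands scale
the CV *targets* before tuning: normalized intensity in [0, 0.25) keeps
fibre velocity and reduces transverse velocity by 25 %; [0.25, 0.5)
reduces transverse by 50 %; [0.5, 0.75) additionally reduces fibre by
25 %; [0.75, 1] reduces fibre by 50 %.  Bands are half-open with exactly
0 in the lowest band, so a just-enhanced element is already slowed
transversely — the band table is authoritative at the edge.

## Protocols

* **New-wave detection**: any activation within 4.2 cm of the stimulus
  site 110–120 ms after onset.  **Reentry**: any activation within 1 cm
  of the site later than 300 ms after a beat, watched over an 800 ms
  horizon.  Distances are Euclidean from the site centre.  These defaults
  assume ventricle-scale geometry; both are parameters, and desk-scale
  tests shrink the window with the domain.
* **ERP binary search** from bounds {200, 450} ms at 10 ms resolution
  (a package choice: coarser than the solver, finer than clinical
  decrements).  Probes branch from a checkpoint taken at the minimum
  coupling interval after the previous beat; the extrastimulus is
  delivered at the capturing end of the bracket.
* **PES**: 3 preconditioning beats at 600 ms, then up to 3 extrastimuli
  at the ERP found from the evolving state, stopping at the first
  reentry.
* **TAT**: beats at coupling intervals 3 × 600, 350, 270 ms; the
  transmural activation time of each of the final three beats is the
  delay from stimulus onset to the first activation of the vertex nearest
  the measurement site on the opposite surface (NaN with a warning if the
  wave never arrives).
* **Transient block**: the 38 × 38-box, 0.25 mm triangular mesh carries a
  row of ten plus-shaped crosses of split edges (one edge per arm).  The
  crosses are laid out with uniform 2-box gaps and the outermost arm tips
  on the lateral boundaries, so the row spans the full width and a
  wavefront can only pass through the inter-cross gaps — with open
  margins the experiment would be vacuous, since both topologies would
  conduct around the row.  Conductivity is tuned to an effective
  17 cm/s; stimuli at 0 and 340 ms halfway across the bottom edge; a wave
  "crosses" when any vertex two element rows above the cross row
  activates within 300 ms of its stimulus.

## Synthetic data

No patient geometry is distributable, so all substrates are generated:
structured triangular grids, structured tetrahedral slabs (5-tet cell
decomposition with alternating parity so faces match; constant or
user-supplied orientation triads), small worked-example stars for the
splitting algorithm, and a radially decaying intensity field
(`I = I_ref + (I_max − I_ref)·max(0, 1 − (r/radius)²)`, optional seeded
jitter) standing in for an LGE-CMR enhancement zone.  These emulate the
*local* features that drive the method — an enhanced subregion with
graded intensity, sheet-aligned cleft preference, two mesh resolutions —
but not the patient-specific wall geometry, fibre rotation, or the
clinical enhancement distribution.  Passing tests therefore establish the
correctness of the algorithms and the qualitative mechanisms (tightness,
transient block, activation delay growing with density and rate), not
patient-level quantities such as absolute transmural activation times or
reentry incidence curves, which require the unavailable imaging-derived
geometry.

## Numerical choices and degenerate inputs

* Meshes are validated for index bounds, positive measures and
  orthonormal triads (1e-8); non-manifold faces (three owners) raise.
* The ERP bisection keeps probes on the resolution grid and returns an
  adjacent (fail, capture) pair; bounds that do not bracet the
  threshold raise a bracket error rather than extrapolating.
* Velocity measurement requires at least 3 activated vertices and a
  positive slope; tuning aborts after 25 iterations with its history.
* Problem sizes used by the shipped tests and the acceptance script —
  12 mm strands, the 38 × 38 grid, slabs of a few hundred to a few
  thousand elements, 20 seeds × 3 densities for the audit sweep — were
  chosen as the smallest substrates on which each mechanism is cleanly
  expressed.

## Known limitations

* Clefts are perfect insulators; partially resistive interfaces and
  deliberately leaky networks are out of scope (the leaky test assignment
  exists only to demonstrate the failure mode).
* Fibrosis faces are sampled independently; no spatially correlated
  textures or replacement fibrosis by element removal.
* No bidomain electrics, ECG, mechanics, or membrane remodelling in the
  fibrotic zone; a single epicardial cell population.
* The 2D cross-row layout is a reconstruction: the row must span the
  domain for the block experiment to probe topology, and the uniform
  2-box gap is the unique such layout for ten crosses on a 38-box grid.
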