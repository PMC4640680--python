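# Methods

## Forward model

Photon transport is simulated as weighted packets on a conforming
tetrahedral mesh.  Steps are sampled as s = −ln ξ / μt with
μt = μa + μs and μs = μs′/(1−g); straight segments are ray-traced across
element faces using precomputed outward face planes and face-adjacency,
so the containing element is always known.  At each interaction a
fraction μa/μt of the packet weight is deposited and the rest scatters
through a Henyey–Greenstein polar angle (inverse-CDF sampling; the g = 0
branch is isotropic) and a uniform azimuth.  Packets below the weight
floor 10⁻⁴ play Russian roulette with survival probability 0.1 (the
standard MCML values).  At the external boundary the unpolarized Fresnel
reflectance for n_tissue vs n_air = 1 decides specular reflection versus
escape; launches are collimated pencil beams with no entry loss.  Elapsed
time advances by (path length)·n/c with c = 0.299792458 mm/ps; packets
whose time exceeds the gating window terminate.

The fluence estimator is absorption-weighted deposition: the deposited
weight at an interaction is spread to the four vertices of the containing
element by the barycentric coordinates of the interaction point, and
nodal fluence is deposit / (μa · nodal volume · photons launched), with
the nodal volume the quarter-share of incident element volumes.  Gate
values are therefore time-integrated fluence per gate; continuous-wave
fluence is their plain sum.  A track-length estimator would reduce
variance in low-absorption media but complicates gate attribution across
a segment; the absorption estimator keeps the per-gate bookkeeping exact
and validates against the diffusion closed form to within ~10% (see
below).

The kernel is numba-jitted, serial, float64 throughout, and
bit-reproducible for a given seed.  Weight is conserved exactly: every
launched packet ends in one of the deposit, boundary-escape,
roulette-kill, or gate-window-expiry ledgers (the test suite checks the
budget to 10⁻⁹ relative).

Validation: (i) the CW fluence of a pencil beam on a 40×40×20 mm slab
agrees with the extrapolated-boundary diffusion point-source solution —
μeff = sqrt(3 μa (μa+μs′)), source depth 1/μs′, extrapolation length
2AD with A from the Groenhuis polynomial for the index mismatch — to
within 15% at 5 mm depth; (ii) forward and adjoint runs on a mirrored
slab agree within Monte Carlo scatter (reciprocity); (iii) nodal noise
scales as N^(−1/2).

## Jacobian assembly

The sensitivity of a detected fluorescence gate to the yield at node r
is the double temporal convolution of the source Green's function, the
adjoint (detector-launched) Green's function evaluated at the same node,
and the lifetime decay exp(−t/τ).  Discretization is a left-endpoint
Riemann sum with Δt equal to the gate width, evaluated by FFT along the
gate axis (linear, zero-padded); the test suite pins it to a brute-force
triple-loop reference at 10⁻¹². No 1/τ normalization is applied to the
decay kernel — W scales like τ for large τ, which only affects the
absolute scale, not relative TPSF errors.  Measurements are
U_F[k] = Σ_r W[k,r] η(r) V(r) with V the nodal volume shares.

## Solution fields and the size map

Five sensitivity-derived fields (row sum of the Jacobian, its log, the
per-row-normalized sum, the global-mean-contrast "curvature"
u_i = S_i − mean_{j≠i} S_j, and its log) and two geometry fields
(minimum optode distance; Beer–Lambert attenuation exp(−μ·distance) with
μ defaulting to μa + μs′) rank nodes for coarsening.  All are
"coarsen-low" except plain distance, whose axis is mirrored before the
map.

The size map compares each value to T_lo = 0.2 × median and
T_hi = 8 × T_lo: below T_lo the node gets the maximum size factor, above
T_hi the minimum, and between them the exponential
y(x) = max_sf · (min_sf/max_sf)^((x−T_lo)/(T_hi−T_lo)), the y = p·aˣ
family fixed by requiring continuity at both clamps (any other constant
choice would produce a discontinuous size field at the thresholds).
Log-family fields can have a nonpositive median, which makes the
thresholds meaningless; the map raises a diagnostic error, with an
opt-in shift-to-positive fallback, rather than proceeding silently —
this is exactly the instability that makes the log fields less robust in
practice.

## Mesh adaptation

Adaptation is iterative edge collapse (coarsen) and edge split at the
midpoint (refine); face and region operations are omitted — edge
operations alone span the isotropic coarsen/refine space.  Candidacy
follows the size factors: an edge is a collapse candidate when its mean
endpoint size factor exceeds ~1.11 (the inverse of the 0.9 collapse
ratio) and a split candidate below ~0.71; a unit size field is an exact
fixed point.  Candidates are processed shortest-relative-length first
(collapses) and longest first (splits), with deterministic node-pair
tie-breaks, and every successful operation freezes its neighborhood for
the rest of the pass, keeping passes local and order-independent.

Each node carries a reference edge length — its mean incident edge
length on the *initial* mesh, transported across iterations through the
transformation matrix like any nodal field.  The target length of an
edge is the mean of (reference length × size factor) of its endpoints,
and the overshoot guard rejects any collapse that would leave an edge
longer than √2 × its target.  Anchoring targets to the initial mesh
bounds the converged element size (≈ √2 × size factor × the original
local spacing) and gives the loop a genuine fixed point; targets based
on the current mesh would compound per iteration and coarsen without
bound until only the validity guards stall the process.

Collapse guards, in order: boundary topology (a boundary node may only
merge into another boundary node with which it shares a boundary face;
merging a boundary node into an interior node is rejected), element
inversion (any remapped element with nonpositive signed volume),
quality (radius-ratio quality 3·r_in/R below the floor 0.02), duplicate
elements, face-count conformity (no face may gain a third incident
element), overshoot, and a cumulative boundary volume-drift budget of
1.8% of the initial mesh volume.  Interior collapses conserve volume
exactly — the cavity around the removed node is retiled against the same
outer surface — so drift only accrues from collapses on curved boundary
patches.

The loop recomputes the solution field on every new mesh (Jacobian
recipes from the analytically rescaled Jacobian, geometry recipes from
geometry) and stops at convergence (node and element counts both
unchanged over an iteration), when the maximum element volume reaches an
optional cutoff (recorded at the first offending iteration), or at the
iteration cap (default 30).  The per-iteration log (nodes, elements,
max element volume, splits, collapses) exports to CSV.

## Jacobian rescaling

The transformation matrix T (input nodes × output nodes) implements
three cases per output node: carried (an input node within
10⁻⁹ × bounding-box diagonal), interior (inverse-distance weights over
the 4 vertices of the enclosing input element, found by deterministic
brute-force point location with lowest-element-index tie-breaks), and
exterior (the 4 nearest input nodes, exact KD-tree queries).  Zero
distances degenerate to the carried case; no distance cap is applied for
exterior nodes.  Columns are renormalized to sum to exactly 1, so
constant fields are preserved and interior-case values stay within the
input range (convex weights).  Rescaling right-multiplies every
(pair, gate) Jacobian slice by T; chained adaptations compose as
T₁·T₂ = T.  Barycentric (linear shape function) interior weights are
available as an explicitly flagged comparison mode, not the primary
path.

## Phantoms

The slab is a structured grid of boxes, each cut into the same 6
tetrahedra (Kuhn subdivision), so the mesh conforms and its volume is
exact.  The slice phantom emulates a ~4 mm thick torso cross section: an
ellipse (default semi-axes 12 and 8 mm — mouse-torso scale) is
triangulated from a boundary ring plus an interior grid (Delaunay on a
convex domain), then extruded in layers, each prism split into 3
tetrahedra by a diagonal rule keyed on global node ids that guarantees
conformity.  At h = 1 mm this gives 1660 nodes / 7188 elements, a
deliberate match to the scale of a mouse-torso cross-section mesh.
Seven sources fan over the +y half of the mid-plane boundary ring
(polar angles π/4…3π/4) with seven detectors mirrored on −y —
transmission geometry with source–detector separations of at least the
minor axis.  Optodes snap to boundary nodes and point inward.  Optical
properties are homogeneous mouse-tissue NIR values: μa = 0.3 cm⁻¹,
μs′ = 15 cm⁻¹, g = 0.9, n = 1.37 (converted to mm⁻¹ internally).
Phantom generation has no randomness: identical parameters give
bit-identical meshes.

What the phantoms do *not* emulate: anatomically heterogeneous optical
properties, curved organ boundaries inside the domain, and realistic
instrument response functions.  Passing tests therefore demonstrate the
adaptation/rescaling machinery and transport physics on a homogeneous
convex domain, not performance on anatomical atlases — though external
meshes can be loaded through the TetGen/VTK readers.

## Problem sizes and defaults

Default gating is 40 gates of 50 ps (0–2 ns), covering the full TPSF of
a ~16 mm transmission path.  The fluorophore lifetime default is
τ = 1 ns.  The headline fidelity figure uses 10⁷ photons per optode;
accuracy studies in the test suite use 10³–10⁶ photons, where the mean
central-node error e(r) against a 10⁶-photon reference falls from
~117% to ~15% — the N^(−1/2) regime — and the adaptation studies run on
the 1660-node slice.  These sizes were chosen so a full validation runs
on a single desktop core in minutes while leaving every scaling trend
clearly resolved.

## Known limitations

- Homogeneous optical properties only; per-region properties would need
  per-element property arrays in the transport kernel.
- The absorption estimator is noisy where μa is very small; a
  track-length estimator is the documented alternative.
- Collapse candidacy uses node size factors, not an anisotropic metric;
  thin domains stall coarsening in the thickness direction by quality
  and boundary guards rather than by an explicit thickness target.
- The adaptation pass semantics (ordering, freezing, guards) are this
  package's own deterministic construction; commercial mesh adapters
  make different micro-choices and will not reproduce identical meshes.
- Exterior-case transfer weights are uncapped inverse distances; output
  nodes far outside the input mesh would extrapolate poorly (not
  encountered in the coarsening workflows here).
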