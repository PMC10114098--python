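# Methods

This note documents the models, numerical choices and known limitations of
`vita`. It complements the README's overview with the detail a user needs
to judge what a result does and does not show.

## Eikonal model

Activation times obey ∇tₐᵀ V ∇tₐ = 1 in the conducting myocardium with
tₐ = t₀ on the stimulus set. Under transverse isotropy the squared-velocity
tensor is V = vₗ² l lᵀ + vₜ² (I − l lᵀ) from the per-element longitudinal
fiber direction l; the transverse direction is implicit. Defaults:

| parameter | default | unit | meaning |
|---|---|---|---|
| `vl_healthy` | 0.50 | m/s | conduction along the fiber, healthy tissue |
| `vt_healthy` | 0.16 | m/s | conduction across the fiber, healthy tissue |
| `v_bz` | 0.16 | m/s | isotropic conduction in the border zone |

1 m/s ≡ 1 mm/ms, so coordinates in mm give times in ms. Scar elements are
removed from the solve domain; nodes incident only to scar read +∞.
Distance fields are the same solve with V = I (units mm).

### Discretization

The solver is a fast-iterative scheme with a label-correcting worklist.
Each node's arrival is minimized over its incident tetrahedra: on the face
opposite the node, the arrival t(λ) + √(eᵀ V⁻¹ e) is minimized exactly
(closed form via the face Gram matrix), falling back to the three edge
minimizations (quadratic roots) and vertex updates when the face minimizer
leaves the face. This local solver is exact — it was validated against
dense brute-force minimization over the face — and the scheme needs no
global causal ordering, which keeps it robust on obtuse tets.

Numerics:

* Convergence: a node is re-queued only when its value improves by more
  than 1e-3 ms (scaled by the model's peak velocity so that multiplying all
  velocities by c reproduces the identical update sequence scaled by 1/c —
  the homogeneity invariant holds to the last bit for binary c).
* Worklist cap: 100× node count queue pops; exceeded ⇒ diagnostic error.
  In practice convergence uses ~3–5 pops per node.
* Accuracy: planar fronts aligned with the lattice are reproduced exactly
  (recovered speeds 0.500/0.160 m/s to machine precision). Point sources
  carry the usual first-order error concentrated near the source; with a
  source ball initialized from the closed form (source factoring), the
  L∞ error against √(xᵀ V⁻¹ x) decreases linearly with edge length
  (≈ 23 % at 1.6 mm → ≈ 14 % at 0.8 mm → ≈ 8 % at 0.5 mm for the 3.1:1
  anisotropy; isotropic errors are ≈ 8 %/4 % at 1.0/0.5 mm). Edge-graph
  Dijkstra with edge cost √(uᵀ V⁻¹ u) is always an upper bound.
* Pacing by location selects all conducting nodes in a ball; an empty
  selection is an error, as is a source set wholly inside scar.

## Synthetic substrates

The generators are pure functions of their parameters (no randomness) so
every downstream stage is testable against constructed ground truth.

* `make_slab(dims, edge, fiber)` — structured grid of cube cells, each cut
  into 6 tets along a common diagonal (conforming across cells).
* `embed_scar(mesh, spec)` — centroid-in-box classification into scar,
  channel and optional border-zone rim. Consequence: staircase boundaries.
  **Important:** a box face that falls mid-cell is porous — of a cell's six
  tets, some centroids land on each side — which lets wavefronts leak
  around an insulating cut. The shipped presets therefore use box faces
  commensurate with the default 0.8 mm grid (slab 40 × 9.6 × 4.8 mm, scar
  x ∈ [12, 28], y ∈ [1.6, 8.0], transmural; channels 1.6 mm wide), giving
  watertight walls. The 16 mm channel length keeps reentry loops
  comfortably above the 50 ms sustained-VT floor (loop times ≈ 71–92 ms at
  the default velocities), representative of clinical isthmus dimensions.
  At other edge lengths the walls may again be porous; the resulting
  micro-fragments are handled by the combine step, emulating fibrosis.
* `make_ring(r_in, r_out, h, edge)` — annular prism with circumferential
  fibers; the unique non-contractible loop has mid-circumference
  2π(r_in + r_out)/2, and an edge-graph Dijkstra oracle gives the exact
  discrete loop length for round-trip-time validation.

What these fixtures do **not** emulate: ventricular anatomy and wall
curvature, rule-based fiber rotation, diffuse (non-corridor) fibrosis,
image-derived scar geometry. Passing tests show the pipeline's topological
and timing logic is correct on idealized substrates, not that it segments
or models a real ventricle.

Note that the two conducting strips between the scar block and the slab's
long edges are themselves corridors; the pipeline legitimately detects and
ablates their exits too, which is why the worked example reports more exit
sites than channels.

## Isosurface splits and exit sites

Level sets at d = k·d_iso (default d_iso = 1 mm, matching the fixture
discretization) are triangulated by marching tetrahedra over conducting
elements with all-finite nodal values; the half-open convention (field ≥ d
counts as distal) makes fragment supports deterministic. Fragments are
edge-connected triangle components; per level, the largest-area fragment
(ties: lowest id) is dropped and the rest are candidates, emitted
individually plus, where two or more exist, as their union (micro-fragment
handling). Downstream/upstream links come from steepest ascent/descent
walks along the conducting edge graph seeded at supporting nodes (strictly
monotone steps, ties to the lowest index, step cap = node count); combined
candidates inherit the union of their members' links. Exits are candidates
with no downstream link, ordered by (level, id).

Caveats, by construction of the largest-fragment heuristic:

* A symmetric source (slab center, face center) splits level sets into
  equal components — near the source or as equal shrinking islands near
  the field maximum — producing candidates on scar-free tissue. These
  carry no reentrant loop, so induction discards them (RTT = +∞); the
  scar-free guarantee "no sustained circuits" holds for any pacing, while
  "no splits at all" holds for the corner pacing sites the slab protocol
  uses.
* Exit sites can sit mid-channel or beyond the anatomical mouth where
  opposing wavefronts collide; this is accepted behaviour and the lesions
  still transect every loop through the corridor.
* No topology analysis of splitting/rejoining conduction paths is done.

## Induction and round-trip time

A block is imposed by excluding from the solve every tetrahedron that
contains a straddling support pair of the exit surface — a one-element-
thick decoupling layer across which no flux can pass — and removing those
edges from the node graph used for connectivity checks. Default
orientation stimulates the distal face (t₀ = 0) and reads the earliest
arrival on the proximal face as the RTT; the flag `flip` swaps faces and
yields the opposite-chirality circuit (same RTT within solver tolerance,
reversed propagation). Which face the block "should" stimulate is a free
choice; both orientations are exposed and the pipeline's chirality policy
(`default` or `both`) controls whether the mirror circuit is simulated.
RTT scales exactly as 1/c under velocity scaling and is bracketed by
edge-graph Dijkstra loop bounds. Circuits with RTT below `rtt_min`
(default 50 ms) are non-sustained and dropped.

## Uniqueness discrimination

Activation maps are compared as cyclic phases (AT mod RTT)/RTT on the
nodes both maps cover, shifted so the first map's earliest-activated node
has phase 0 in both, then Pearson-correlated. Two refinements matter:

* Nodes on either circuit's block faces are excluded: their induced AT
  jumps from 0 to one full cycle across the (artificial) line of block,
  so their phase is an artifact of where the block was placed. Without the
  exclusion, opposite-chirality ring circuits correlate at ≈ −0.93 instead
  of the continuum −1.
* The comparison is direction-dependent (the anchor comes from the first
  argument, and shifting phases mod 1 relocates the wrap point), so the
  greedy selection's convention — newly visited circuit against each
  already-kept circuit, visiting in descending RTT — is also the
  convention under which "kept pairwise correlation ≤ threshold" is
  guaranteed and should be re-evaluated.

Threshold 0.8 (above it: redundant); phase normalization by each
circuit's own RTT makes circuits of different period comparable. QRS-trace
correlation (mean per-lead Pearson) is provided as an advisory mode only;
with three 120°-spaced leads, a rotating dipole of reversed chirality
gives a lead-averaged correlation near zero, so the ECG discriminates
chirality poorly — the vectorcardiogram loop orientation (signed area of
the I–II trajectory), which flips sign exactly, is the robust read-out.

## Ablation

Exit sites are visited in descending induction-time RTT (ties by circuit
id); each is re-tested on the cumulatively ablated substrate and made
permanent — its cut elements relabelled scar — whenever any finite return
arrival exists. The optional `rtt_min` argument instead requires the
re-tested RTT to reach the sustained floor, exposed because the default
rule also ablates very short non-sustained circuits. A single forward
pass is made; skipped sites are not revisited. Verification re-runs the
entire pipeline on the ablated mesh from the original pacing sites and
succeeds iff no sustained circuit remains; this is asserted on all shipped
fixtures, and truncating a plan to its first lesion on the two-channel
slab demonstrably leaves inducible VT.

## ECG surrogate

No ionic model is solved. Each node's transmembrane voltage is a smooth
parametric template — tanh upstroke (1.5 ms), plateau at +30 mV from
−85 mV rest, sigmoidal repolarization centred at APD = 201.5 ms with a
40 ms width — shifted by the node's activation time (modulo RTT for one
VT cycle). Far-field potentials use the infinite homogeneous volume
conductor approximation: φₑ(e) = −k Σ V_el ∇Vm·(e − c_el)/|e − c_el|³
with per-element constant gradients from the linear shape functions.
Amplitudes are arbitrary units (k is not calibrated; lead II is normalized
to peak 1 by default). Electrodes default to an Einthoven triangle on a
sphere of 3× the bounding-box diagonal and must lie outside the tissue.
Lead II is assembled as I + III so the Einthoven identity is exact in
floating point. Note that with RTT shorter than the APD, the template
never fully repolarizes within a cycle — the expected regime for these
short reentrant circuits.

## Determinism and problem sizes

Every stage is deterministic: fixture generation takes no random numbers,
all orderings carry explicit tie-breaks, and two identical runs produce
identical reports (asserted bitwise on times). The run configuration
accepts a seed only to document invocations. The shipped analyses use the
0.8 mm fixture discretization (≈ 4.6 k nodes, 27 k tets per slab), where a
distance solve takes well under a second and a full four-site pipeline run
with verification completes in seconds on one CPU; the same code paths
scale to finer meshes linearly in solver work.

## Known limitations

* Purely anatomical: functional (repolarization-gradient) block and the
  resulting functional VTs are invisible to this approach.
* Exit-site localization inherits the collision caveat above; lesions are
  one element thick and not sized to clinical ablation physics.
* The Eikonal front has no wavefront curvature or source-sink effects;
  velocities are piecewise constant per region.
* The φₑ recovery ignores torso geometry and conductivity inhomogeneity;
  traces are for waveform-shape comparison, not amplitude prediction.
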