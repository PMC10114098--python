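# vita

Virtual induction and treatment of anatomical reentry on labelled
tetrahedral heart-tissue meshes.

After myocardial infarction, surviving corridors of conducting myocardium
("isthmuses") threading a non-conducting scar form the anatomical substrate
of ventricular tachycardia (VT): a wavefront that enters the corridor, exits
into bulk myocardium and returns around the scar re-excites the tissue
perpetually. Catheter ablation aims to destroy the corridor exits.
Predicting which corridors can sustain VT, and which minimal set of lesions
silences all of them, normally requires expensive reaction-diffusion
simulation. `vita` answers the same questions with purely topological and
Eikonal computations, fast enough for near-real-time planning, for
researchers in computational cardiac electrophysiology.

## Method

Given a tetrahedral mesh with per-element fiber directions and region tags
(healthy / border zone / scar), the pipeline runs, for each pacing site:

1. **Distance field.** Solve the anisotropic Eikonal equation
   ∇tₐᵀ V ∇tₐ = 1, tₐ = t₀ on the stimulus set, where
   V = vₗ² l lᵀ + vₜ² (I − l lᵀ) is the squared conduction-velocity tensor
   (defaults vₗ = 0.50 m/s, vₜ = 0.16 m/s, isotropic 0.16 m/s in the border
   zone; scar does not conduct). With V = I the solve yields the geodesic
   distance through conducting tissue.
2. **Split isosurfaces.** Extract level sets of the distance field every
   d_iso = 1 mm by marching tetrahedra. Inside an isthmus the confined
   wavefront appears as an extra connected component; at each level the
   largest fragment (the bulk front) is dropped and the rest are "split"
   candidates, tested individually and combined.
3. **Exit sites.** Link candidates of consecutive levels by steepest
   ascent/descent of the field along the edge graph; candidates with no
   downstream neighbour are exit sites (no upstream neighbour: entrances).
4. **Induction.** For each exit, decouple the tissue across the exit
   surface (unidirectional block), stimulate one face at t₀ = 0 and read
   the round-trip time (RTT) — the earliest return of the wavefront at the
   opposite face. Circuits with RTT ≥ 50 ms count as sustained VT.
5. **Unique VTs.** Pool circuits over all pacing sites, convert each
   activation map to cyclic phase (AT mod RTT)/RTT, align starting
   locations, and drop circuits whose Pearson correlation with a kept
   circuit exceeds 0.8. Opposite-chirality circuits correlate near −1 and
   stay distinct.
6. **Ablation.** Visit exit sites by descending RTT; wherever reentry is
   still inducible on the partially ablated substrate, make the block
   permanent (a thin transmural lesion). A full pipeline re-run on the
   ablated mesh verifies that nothing sustained remains.
7. **ECG surrogate (optional).** A reaction-Eikonal step shifts a
   parametric action-potential template by each node's activation time and
   recovers far-field potentials φₑ under an infinite-volume-conductor
   assumption, yielding Einthoven limb leads I, II, III for one VT cycle.

Everything is deterministic; meshes are read and written in openCARP
plain-text format (`.pts`/`.elem`/`.lon`, per-node scalars as `.dat`).

## Worked example

Built-in synthetic substrates emulate the idealized infarct anatomy: a
40 × 9.6 × 4.8 mm slab with fibers along x, a transmural scar block, and
one (`slab1ch`) or two (`slab2ch`) conducting channels through it, plus an
annular ring whose unique reentrant loop has closed-form length.

```sh
vita run --preset slab1ch --corners --out results/
```

pacing the one-channel slab from its four corners prints (abridged):

```json
{
  "per_site": [{"site": 0, "levels": 39, "split_levels": 18,
                "candidates": 50, "exits": 3}, "..."],
  "induced_vts": 12,
  "all_rtts_ms": [92.4, 92.4, 90.8, 92.4, "..."],
  "unique_vts": 3,
  "ablated_sites": [56, 58, 57, 61],
  "n_lesion_elements": 198,
  "verification_success": true
}
```

Each pacing site finds exit sites where a confined wavefront terminates
(the channel plus the two narrow strips between scar and slab boundary);
all twelve induced circuits are sustained (RTT ≈ 91–92 ms, well above the
50 ms floor), reduce to three unique VTs, and four permanent blocks
(198 lesion elements) render the substrate non-inducible —
`verification_success` is the verdict of a complete re-run from all four
pacing sites on the ablated mesh.

The same stages are available as library calls (`vita.run_vita`,
`vita.solve_activation`, `vita.extract_level_sets`, ...) and as the
subcommands `vita fixtures`, `vita solve`, `vita ecg`.

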