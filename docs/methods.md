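# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `bivtwin`, in the order the pipeline runs them.

## Geometry and meshing

Meshes are built on structured hexahedral grids subdivided into six
tetrahedra per cell (Kuhn subdivision). The grid spacing is chosen so the
*mean unique-edge length* of the subdivision matches the requested edge
length (the mean over axis edges, face diagonals and body diagonals is
≈1.282× the spacing); generators therefore honour the request within
±20 % by construction, and slab volume is conserved exactly because the
grid tiles the requested box.

The biventricular geometry is an idealized implicit solid: a thick-walled
LV half-ellipsoid plus an offset, thinner RV shell wrapped around it,
truncated at the base plane. Cells whose centroids fall inside the solid
are kept; the kept set is then repaired to *well-composedness* (no
diagonal voxel contacts in any 2×2 or 2×2×2 block) by filling critical
voxels, which guarantees a 2-manifold boundary — the boundary of the
default geometry is a single genus-0 surface (Euler characteristic 2),
and the test suite checks this. Boundary nodes are classified against the
implicit surfaces to produce the `lv_endo`, `rv_endo`, `epi`, `base`,
`apex` and `rv_septum` tags; the septal RV-cavity face (on the LV
epicardial level set but facing the RV cavity) is tagged explicitly.
Because the boundary is stair-stepped, tag-to-surface distances carry
O(h) noise; geometric assertions in the tests use a two-cell guard band.

The study scale uses sub-0.4 mm meshes; here the desk-scale defaults are
1000 µm (slab) and 2000–4000 µm (biventricular). The conduction-velocity
convergence test documents the cost: the 1 mm strand velocity is within
15 % of a 250 µm reference.

## Anatomy labelling

Transmural and apicobasal coordinates are P1 finite-element harmonic
interpolants (Laplace–Dirichlet labelling) with zero-flux conditions on
untagged boundary. On biventricular meshes the transmural coordinate
blends two solves (LV-endo→epi and RV-endo→epi) by the pointwise maximum
of the normalized solutions, which assigns the septum to the LV problem.
Layers are cut at *volume-weighted* quantiles of the coordinate —
the stated proportions could alternatively be read as coordinate-range
fractions; volume weighting is the default here and the alternative is a
one-line change at the call site. Quantile ties break by node index so
the partition is deterministic.

Infarct zoning uses full-width-half-maximum thresholding of a nodal
intensity field: scar above half the affected-zone maximum, border
between the remote-tissue maximum and that threshold. Masks are nodal; a
voxel-mask-to-node interpolation (radial basis functions, as used for all
scattered-data transfer here) precedes it when needed. The intensity
surrogate uses additive Gaussian noise — no noise model is prescribed for
this kind of data, and Gaussian is the conventional default.

## Fiber fields

Diffusion tensors are fitted per node by ordinary least squares in the
log domain (−ln(S/S₀)/b = gᵀDg), with no positivity projection; negative
eigenvalues from noisy fits are clipped only inside the fractional-
anisotropy evaluation and flagged. The fit is exact on noiseless signals
and unbiased under zero-mean log-domain noise (checked by simulation).

Rule-based fields build a local wall frame from the normalized gradient
of the transmural coordinate (transmural direction), the apicobasal
gradient orthogonalized against it, and their cross product
(circumferential). The helix angle interpolates linearly from α_endo at
coordinate 0 to α_epi at 1, per ventricle, septum treated as LV, sheet
tilt fixed at 0 (transverse isotropy). Degenerate-gradient elements
inherit the nearest valid frame.

The fiber-field comparison metric Θ̄ averages the angle between
longitudinal directions folded to [0°, 90°] via the absolute dot
product, because fiber sign is unobservable; a `fold=False` switch
evaluates the literal signed arccos instead. Calibration fixes one
ventricle's angles and sweeps the other's over [+90°, −90°) in 10° steps
(18×18 = 324 candidates), refines ±10° in 1° steps, then repeats for the
other ventricle. Ties resolve to the smallest-magnitude angle pair. The
search provably returns the best evaluated candidate, and recovers
planted off-grid angles to 1°.

## Conduction system

The His bundle is a polyline over surface-graph geodesics (Dijkstra on
the endocardial edge graph, falling back to the full boundary graph when
a tagged patch is fragmented) between an atrioventricular-node landmark,
a bifurcation, and three branch endpoints (LV anterior/posterior, single
RV). Purkinje networks grow from the branch endpoints as binary fractal
trees constrained to the surface: each branch advances a few straight
steps in the local tangent plane (snapping to the surface), then
bifurcates about the local normal; branch length shrinks geometrically
with seeded log-uniform jitter. Defaults (0.8 cm initial length, ratio
0.8, 35° branching, 5 generations, 3 steps per branch) give a junction
density of roughly one per 25 mm² on the synthetic ventricles. Junction
placement excludes the basal band (apicobasal coordinate ≥ 0.8 — the
basal exclusion extent is not quantified anywhere, so a configurable
20 % band is used) and the RV septal/posterior regions.

Depth projection moves the whole tree into the subendocardial shell (the
outer half of the endocardial layer, coordinate in [c₁/2, c₁]) and
relocates a seeded 75 % of end branches to the intramyocardial shell
(middle third of the midmyocardium). Architecture variants: `rvs` adds
uniform septal junctions, each stitched through a short (0.8 mm)
penultimate stub so its lead time reflects the junction rather than the
attachment segment; `ap`-type variants move the LV bundle-branch
endpoints apically (apicobasal ≤ 0.3) *before* growth, since relocating
grown terminals would stretch unphysical last segments; `ap-e` flattens
everything back to the endocardial surface; `mi` retains a seeded 42 % of
affected-zone junctions per depth layer and redistributes them 51:36:13
over subendocardial/intramyocardial/epicardial shells by largest-
remainder apportionment. Trees remain connected and acyclic under every
variant (leaf-only pruning).

Coupling collects all mesh nodes within the junction radius of each
terminal (k-d tree, identical to brute force). The anterograde metric
counts junctions with at least one coupled node activating within
[0, 1.5] ms of the terminal's parent node. The junction conductance
default (8×10⁻³ cm³/ms, split equally over the coupled nodes) and the
conduction-system taper length (0.02 cm) were chosen so that effective
junction lead times at the selected 0.5 mm radius are ≈1 ms — the
anterograde window itself implies sub-1.5 ms delays at the operating
point — and the characteristic rise-then-fall of anterograde coupling
with radius emerges on the slab testbed.

## Cell model and monodomain propagation

The default reaction term is a two-current phenomenological action
potential (Mitchell–Schaeffer type) mapped to millivolts
(V = −84 + 114·u), extended with two multipliers mirroring the ionic
conductances that matter for infarct remodelling: `apd_control` scales
the gate-closing rate (inward-rectifier analogue; APD strictly decreases
as it grows) and `excitability_control` scales the fast inward current
(sodium analogue; upstroke velocity and conduction slow as it falls).
Parameters (τ_in = 0.1, τ_out = 6, τ_open = 120, τ_close = 68.5 ms,
u_gate = 0.13) were set once so that the prepaced APD₉₀ is ≈213 ms at a
650 ms cycle length and planar conduction runs at ≈72 cm/s at the
healthy diffusion coefficient — the operating point of the study-grade
porcine ionic model, without reproducing its equations (the `CellModel`
slot accepts externally supplied models). The resting state (u=0, h=1)
is an exact fixed point. In the border-zone regime (excitability 0.38,
diffusion 0.000882 cm²/ms) the same cell conducts at ≈34 cm/s,
consistent with the border-zone velocities the calibration targets.

Prepacing paces a 0-D cell until at least `min_beats` beats and a
beat-to-beat APD₉₀ change below tolerance; model parameters may be
arrays, so a whole batch of cells paces in lockstep (used by the batch
APD tuner). Beats that fail to repolarize within the cycle are censored
at the cycle length — this is how unattainably long targets surface. A
beat with no regenerative upstroke (peak below 90 % of full amplitude)
raises.

Tissue diffusion is P1 FEM with lumped mass; the element tensor is
LDC·(r·I + (1−r)·ffᵀ) with zone-wise LDC and ratio. Scar elements are
dropped from assembly, which *is* the insulating zero-flux condition at
the scar interface; scar nodes are frozen. The conduction system is a
1-D cable (cross-section 10⁻³ cm²) whose coefficient tapers from the
fast CS value to the tissue value along a sigmoid of arc distance to the
nearest terminal. Junctions couple resistively into the global operator.

Integration is Strang splitting: subcycled forward-Euler reaction halves
around a backward-Euler diffusion solve (the two time-step operators are
LU-prefactorized). The step switches between the bounds (default
[0.01, 0.125] ms) by whether any node's |dV/dt| exceeds 10 mV/ms — the
adaptive rule is a package choice; output is sampled at 0.25 ms. At
fixed inputs the integration is bitwise deterministic. Stimuli default
to 80 µA/cm² for 1 ms, i.e. 80 mV/ms at 1 µF/cm²; monodomain scaling
uses surface-to-volume 1000 cm⁻¹ and 1 µF/cm², making 0.0013 cm²/ms
equivalent to 0.13 S/m.

## Calibration loops

APD₉₀ targets are matched by geometric bisection on `apd_control` using
the prepaced APD₉₀, to 0.5 ms. Bounds [0.25, 20]×baseline: below ≈0.25
the cell cannot repolarize within a 650 ms cycle, so longer targets are
reported as unattainable with the bound reached — mirroring the fact
that some experimental repolarization times exceed what any inward-
rectifier scaling can reach. A vectorized variant tunes many regional
targets in one batched bisection. Regional heterogeneity maps assign the
tuned multipliers by transmural × apicobasal labels (modes: uniform,
transmural-only, full 3×3; the 3×3 target table at 650 ms cycle length
is the default).

Border-zone conductivity is fitted on a standardized 2 cm strand at
500 µm (the full-ventricle tuning of the source workflow replaced by a
strand — the self-consistency property, parameter recovery within 10 %
across a decade, is the justification; a curvature-related low bias
relative to full anatomy is possible and noted). Velocity grows
monotonically with the coefficient, so log-space bisection converges;
strand simulation duration adapts to the expected transit time.
Per-subject fits pool by unweighted arithmetic means. The anisotropy
update multiplies the baseline transverse ratio by (1 + relative FA
decrease).

## Signal analytics

The pseudo-ECG evaluates the infinite-medium dipole-source integral by
element-wise P1 gradients and one-point quadrature. Linearity in the
nodal voltages collapses the whole computation into one
(electrodes × nodes) lead-field matrix; uniform voltage gives
identically zero, and the far field matches the point-dipole closed form
(note the kernel ∇(1/‖r−e‖) = −(r−e)/‖r−e‖³ fixes the sign convention;
per-lead normalization later removes scale). The default electrode
layout places limb and precordial electrodes on a 25 cm sphere around
the mesh centroid; rigid rotation + translation implements the
heart-electrode-position adjustment, and the right-leg electrode is
reference-only.

Filtering is zero-phase Butterworth (0.5/40 Hz defaults), baseline set
to zero by subtracting the per-lead median (the zeroing rule is a
package choice), and per-lead normalization to unit maximum absolute
value (the norm choice is config-switchable). Median beats crop around
fiducials (240/538 ms), pick the representative beat maximizing summed
correlation, and take the sample-wise median of beats correlating above
0.9 with it. QRS/T segmentation centers ±50/±100 ms windows on mean (per
lead) peak times, searching the QRS peak in the first 40 % of the beat
and the T peak in the remainder — a stylized delineation sufficient for
simulated beats; real-data delineators are out of scope.

Activation is the interpolated first upward 0 mV crossing (simulations)
or the maximum positive derivative (optical movies); APD₉₀ runs from the
maximum-derivative upstroke to 90 % recovery toward the diastolic level.
Velocity at a site is the mean displacement-over-delay vector to
neighbors within a radius (600 µm at study resolution, scaled to cover
the mesh edge on coarser meshes; 3 pixels on optical grids), with
|ΔAT| < 0.01 ms pairs excluded. This estimator is unbiased only where
the neighborhood is symmetric; grid-edge sites carry a known upward
bias, so quantitative checks use interior sites.

Optical-movie processing: per-pixel 0.4 Hz high-pass for drift, spatio-
temporal Gaussian smoothing with σ doubled where the local SNR estimate
(variance over a median-absolute-difference noise floor) falls below 4 —
the adaptivity rule is a package choice — then per-beat activation/APD₉₀
extraction on each pacing cycle and per-pixel medians across beats.

## Synthetic-data conditions

Generator defaults mirror the study conditions: 2000 Hz ECG sampling
with a 769 ms RR interval; 500 Hz optical sampling at 1000 ms pacing;
diffusion imaging with 15–64 gradient directions at b = 600–1000 s/mm²;
infarct intensity levels (30, 55, 100) a.u. with the bright core well
above twice the remote level. The stylized optical action potential is a
sigmoid upstroke with a plateau and an exponential tail reaching 90 %
recovery exactly at the planted APD₉₀ — enough to exercise map
extraction without an ionic model per pixel. All randomness flows from a
single user seed through `numpy.random.default_rng`; no global state.

What passing tests do **not** show about real data: the generators have
no motion, no fat-coverage signal dropout, no beat-rate variability
beyond Gaussian RR jitter, no spatially correlated imaging noise, and
the idealized ventricles have smooth walls and a single compact infarct.
Forward/inverse round trips certify the analysis code, not the
instrumentation.

## Known limitations

- Desk-scale meshes (1–4 mm) overestimate wavefront width relative to
  study-grade 0.39 mm meshes; on the coarse biventricular mesh the
  junction anterograde percentage is discretization-limited (tens of
  percent rather than >90 %), while the slab testbed at 1 mm reproduces
  the quantitative rise-then-fall.
- The two-current cell has no rate-dependent restitution memory to speak
  of, so prepacing converges in a handful of beats; protocols probing
  restitution need an externally supplied cell model.
- The pseudo-ECG is infinite-medium: no torso conductor, no lead-field
  inhomogeneity.
- Voxel-based ventricular meshing gives stair-stepped surfaces; surface
  tags are classified against level sets and carry one-cell noise.
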