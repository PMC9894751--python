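# Methods

This note records the models, conventions, numerical choices and known
limitations behind `nemaglide`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate and angle conventions

Grids are row-major; physical coordinates are x = column·pixel_size and
y = row·pixel_size with y increasing downward (image convention). All angles
are measured counter-clockwise from +x *in this frame*. Director angles are
line orientations defined modulo π; particle headings live on the full
circle. Chirality labels follow the shoelace sign in this frame: positive
signed area ⇒ "CCW". Any consistent frame works — mirroring all inputs flips
every chirality label, which the tests verify.

## Director extraction (structure tensor)

For a fluorescence image of aligned filaments, the intensity gradient is
perpendicular to the filaments, so the normalized tangent t = (I_y, −I_x)
points along the local orientation. Per node, the orientation is the
principal eigenvector of T = ⟨t⊗t⟩ box-averaged over L×L = 1.3 µm × 1.3 µm
at one-pixel stride. Numerical choices:

- Gradients are central differences after a σ = 1 px Gaussian pre-smooth;
  raw anti-aliased line art has unstable gradients at single-pixel scale.
- Because tangents are normalized, background pixels containing only noise
  would vote with full weight. Pixels whose gradient magnitude falls below
  10% of the 95th-percentile magnitude are excluded; boxes with no
  voting pixels (or an isotropic T) are masked invalid. A constant image
  yields a fully masked field plus a warning, not an error.
- Accuracy depends on filament length in pixels. At 0.065 µm/px (the
  resolution the rendering emulates) the median angular error on rendered
  textures is ~4°; by 0.2 µm/px, where a 0.8 µm filament is only four pixels
  long, end-cap gradients dominate and the error grows past 15°. Tests that
  need accurate round trips render at 0.065 µm/px.
- Core localization of defects re-detected from *rendered* images is limited
  by the 1.3 µm averaging box to roughly half a micron; the 2-pixel figure
  quoted for detection applies to analytically generated fields.

## Q tensor, splay/bend, sampling

Q = S(n⊗n − I/2) stored as (Qxx, Qxy); S ≡ 1 by default ("unit" mode), or
the structure-tensor eigenvalue gap ("coherence" mode). The polarity field
p = ∇·Q/|∇·Q| is normalized per node, so the S convention cancels wherever S
is locally homogeneous.

Splay (∇·n)² and bend |n × ∇×n|² are computed with locally sign-aligned
central differences (each neighbor flipped into the hemisphere of the centre
node), making both maps invariant under arbitrary n → −n gauge flips;
boundary nodes use one-sided differences. For unit directors the bend equals
the squared z-curl, which the radial/azimuthal 1/r² closed forms confirm to
<5% for r > 5 px.

Continuous sampling interpolates (cos 2φ, sin 2φ) bilinearly and
reconstructs the half angle — exact on nodes and safe across the π wrap.
Masked nodes carry zero interpolation weight; positions without valid
support raise an out-of-domain error that the simulator and tracer treat as
a boundary event.

## Synthetic fields

The generator is the standard one-constant multi-defect ansatz
φ(r) = φ0 + Σᵢ kᵢ·atan2(y−yᵢ, x−xᵢ), which has exactly quantized winding:
every loop's winding equals the sum of enclosed charges. Defects landing on
grid nodes are nudged half a pixel so no sampled angle sits on the
singularity. Random configurations rejection-sample positions with ≥10 px
pairwise separation; charges are ±1/2 shuffled to meet the requested net
charge.

Confined discs use the method of images: each interior defect k at complex
position z₀ (from the disc centre) contributes k·arg(z − z₀) +
k·arg(R² − z·z̄₀); on the rim the pair sums to k·θ, so with total charge +1
and a π/2 offset the rim director is *exactly* tangential, while the image
singularities lie outside the disc. This satisfies Poincaré–Hopf
(n₊ − n₋ = 2 enforced) without an elastic relaxation, which the topology
tests do not need. Defect placement depth matters physically: defects
allowed near the rim (`max_radius_frac` ≈ 0.9) produce the edge distortions
that select a single stable handedness of the edge current; deep placements
leave a smooth tangential rim on which both circulation directions survive.

The asymmetric +1/2 texture adds a rotation skew·ramp(r)·cos²(θ/2) to the
canonical comet: zero at the core, saturating past 1 µm, and windowed to the
head side. A *uniform* rotation would co-rotate the comet axis (the axis of
φ = θ/2 + c sits at angle 2c) and produce no asymmetry; the angular window
leaves the axis nearly fixed while the outgoing director meets it at the
requested skew.

Rendering draws anti-aliased line segments (0.8 µm "actin" for textures,
2 µm "rods" for movies at 5 s frame intervals), blurs with a ~0.8 px
point-spread function, and adds Gaussian noise; everything is reproducible
under a seed. The renderer emulates segment placement, optics blur and
camera noise only — no photobleaching, no filament curvature, no density
correlations, no autofluorescence. Extraction and tracking results on
rendered data therefore bound algorithmic error, not all experimental error
sources.

## Defect analysis

Charge density is the per-plaquette winding of the four corner directors
(each increment mapped to (−π/2, π/2]) divided by plaquette area; it sums
over any region to the region's boundary winding exactly, and is quantized
in halves. Detection clusters non-zero plaquettes (8-connectivity), merges
clusters closer than `min_separation` (default 3 µm), and reports the
|charge|-weighted centroid — no sub-pixel refinement beyond the centroid,
with a 2 px position tolerance on analytic fields. The +1/2 axis is the
ring-average (default radius 4 px) of ∇·Q, normalized; for the canonical
comet ∇·Q = (1/(2r), 0), so the axis points toward the side where the
director runs parallel to it. An axis whose ring-averaged |∇·Q| vanishes is
reported as undefined rather than guessed.

## Particle simulation

Euler–Maruyama with the heading updated before the position; every step
displaces exactly v·dt, which doubles as a cheap integrator invariant. The
noise-free alignment obeys tan(φ−θ)(t) = tan(φ−θ)(0)·e^(−2At); the
integrator matches it to <10⁻³ relative error at dt = 0.01 s and converges
linearly in dt. dt defaults to 0.1 s; a guard rejects A·dt ≥ 0.2.

Each particle consumes its own counter-based RNG stream (and its own
initial-condition stream), so trajectories are bit-reproducible and adding
particles never perturbs existing ones. Noise-off runs are expressed as
L_p = ∞.

Boundaries: the continuous equations say nothing about walls, so both a
specular `reflect` (default) and a tangential `slide` rule are implemented
and tested; disc confinement reflects about the local rim tangent. Wall
interactions decorrelate headings, so persistence-length estimation must be
run in an arena much larger than the path length — the estimator flags runs
whose orientation autocorrelation never decays into the fit window
(C ∈ [0.2, 1)) instead of extrapolating. The fit is a through-origin
least-squares line on log C versus arc length with a particle-bootstrap 95%
interval; it recovers L_p ∈ {25, 100} µm within 10% from 200 particles ×
500 µm of path.

## Streamline prediction

Seeds sit at r⁺ + d·p⁺ with d = 2 µm (the single model parameter, exposed
everywhere); the initial direction is n(r_seed)·sign(−n·p). The sign rule
sends the streamline through the parent core and around the comet's hairpin —
the path gliding particles actually take. An exact tie n·p = 0 keeps +n and
flags the seed. Integration is midpoint (RK2) at step = 0.5 px with
direction-sign continuity; termination on entering 1 µm of a *different*
+1/2 core, leaving the valid mask, closing on itself (0.5 µm, direction
agreement > cos 45°), or exceeding 10× the field perimeter. Streamlines are
seeded only at +1/2 defects and stop only at +1/2 cores; −1/2 defects
deflect but do not terminate.

Prediction quality varies with the texture: on dense configurations
(~10 defects per 100×100 µm) the simulated late-time occupancy is enriched
around predicted streamlines relative to randomly re-seeded ones (paired
comparison in the acceptance suite), but individual sparse configurations
can disagree, because away from defects the exit path's continuation is
sensitive to which field line the trace lands on after crossing the core.

## Tracking and flow

Frames are Otsu-binarized (threshold exposed); connected components are
ellipse-fitted via their second moments; only aspect ratio > 2 survives.
Links require distance < 5 µm, mutual nearest neighbours, and area and
length each changing < 20% relative to the earlier contour; matching is
greedy by increasing distance, removing matched contours — the globally
closest remaining pair is automatically mutual-nearest. Tracks do not close
gaps or resolve crossings. Block flow matches local templates by normalized
cross-correlation within a 3.6 µm window on a strided grid, integer
displacements by default with optional parabolic sub-pixel refinement, and
can be masked by the thresholded maximum-intensity projection of the stack.
Pure translations are recovered exactly up to half the search window.

## Pattern metrics

S_v = 2(n·v/|v|)² − 1, gauge-invariant and undefined at zero speed. Pearson
agreement smooths, block-averages to ≤256 px per side, then correlates.
Exit counting uses a dwell-then-gate rule standing in for the paper-style
manual count: a passage requires approaching within 2 µm of the core and is
classified by the transverse sign of the velocity when crossing the 4 µm
gate; the fraction max(n₁,n₂)/(n₁+n₂) ships with an exact binomial p-value
because the counts are small.

Loop detection closes a path where it revisits itself within 1 µm with
direction agreement > cos 45°, keeping the smallest circuit above 10× the
closure tolerance (one orbit, not a multi-wound composite). *Polar* loops —
the ones that must enclose charge +1 — are circuits whose tangent stays on
one alignment branch of the director transported along the loop; noisy
trajectories occasionally close a circuit containing an alignment reversal,
and those are discarded when the minority-branch fraction exceeds 2%
(genuine polar loops measure exactly 0; observed artefacts ≥ 4.5%). The
enclosed charge is the director winding along the positively oriented loop;
defect counts come from point-in-polygon tests. Edge statistics count
tangential-velocity signs inside a band of 0.15·R at the rim, per frame,
with per-group (initial-handedness) radius traces.

## Problem sizes

Default test and acceptance workloads use 100–200 px grids (0.5 µm/px),
10–50 particles, and 10⁴–5·10⁴ steps; rendered-image round trips use
0.065 µm/px patches. These sizes keep every statistic they feed well away
from its pass threshold while completing in minutes on one CPU.

## Known limitations

- The passive nematic is static by assumption; no defect dynamics,
  annihilation, or elastic relaxation.
- The one-constant ansatz and image construction are stand-ins for the
  unknown generator of real textures; they guarantee correct topology, not
  realistic elastic energetics.
- Particles are non-interacting points: no steric alignment between gliding
  filaments, no density feedback on the nematic.
- Extraction accuracy is resolution-limited as described above; tracking
  assumes rods rarely overlap.
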