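# Methods

This note documents the models, estimators and design choices behind the
audit pipeline: what each quantity means, how it is computed, what the
synthetic phantoms do and do not emulate, and where the genuinely open
choices were made.

## Image-quality metrics

All three scores are computed from a CT volume in Hounsfield units (HU) and
a binary arterial mask on the same grid.

**Peri-arterial ring.** "Surrounding non-arterial tissue" is operationalised
as the set of voxels reached by `width` face-connected (6-neighbour)
morphological dilation steps of the artery, minus the artery itself. The
default width is 3 voxels: at typical CTCA resolution (0.3–0.75 mm voxels)
this stays within the immediate peri-arterial tissue without reaching
unrelated structures. The same ring supplies both the tissue mean and the
noise estimate, so a single region definition drives the whole metric family
— an alternative would be a separate background box, but that would
introduce a second, arbitrary region.

**Artery contrast enhancement** (HU) is the artery mean minus the ring mean.
It is invariant to global additive HU shifts and scales linearly with HU
scaling.

**Contrast-to-noise ratio** divides the same contrast by the population
(ddof = 0) standard deviation of the ring. The population convention is a
determinism/simplicity choice and is documented rather than asserted as the
only possible estimator; with rings of thousands of voxels the difference
from ddof = 1 is far below any decision threshold. A piecewise-constant
(noiseless) image has zero ring SD and is rejected as "no measurable noise"
rather than returning infinity.

**Edge sharpness** (HU/mm) is the mean, over arterial boundary voxels, of
the spacing-aware gradient magnitude computed by central differences
(`(v[i+1]−v[i−1]) / 2Δ` per axis, Euclidean norm). Boundary voxels are
artery voxels with at least one face-connected background neighbour;
voxels on the volume border are excluded because central differences are
undefined there. No pre-smoothing is applied, so results are exactly
reproducible and a hand-built step edge evaluates exactly to ΔHU/(2Δ).
Whether boundary averaging should instead sample perpendicular intensity
profiles is an open design question; the voxelwise average is simpler,
deterministic, and monotone in blur, which is the property the audit needs.

## Dice evaluation and ensembling

Tree-level DSC is `2|A∩B|/(|A|+|B|)`; two empty masks score 1.0 by the
agreement convention (documented; never triggered on phantoms containing
vessels). Majority voting marks a voxel foreground only when strictly more
than half of the members do, with exact ties resolved to background — a
conservative choice that a 3-member committee can never trigger. Soft
ensembling thresholds the voxelwise mean probability at 0.5 inclusively, so
behaviour at the boundary is deterministic.

**Per-branch DSC.** Reference trees carry integer branch labels
(LM/LAD/LCx/D1/OM1/RCA). Each predicted foreground voxel is attributed to
the branch of its nearest reference centreline point in world millimetres,
then DSC is computed per branch between attributed prediction voxels and
reference label voxels. This is a voxel-space equivalent of splitting the
tree on a surface mesh and mapping the split back into the image domain; it
removes any mesh dependency. Centreline points shared by two branches at a
junction are deduplicated keeping the first branch listed, making
tie-breaks deterministic and consistent with the phantom's own labelling
rule, so a perfect prediction scores exactly 1.0 on every branch.
How prediction voxels *beyond* the reference tree should be attributed is
not uniquely defined; nearest-centreline attribution is the documented
choice.

## Vessel morphometrics

The geometry stack is a desk-scale replacement for mesh-based vascular
toolkits, built on voxel operations:

1. **Centreline**: the branch mask is thinned to a 3D skeleton
   (Lee's algorithm via scikit-image); skeleton voxels form a 26-connected
   graph weighted by world distance, and the centreline is its longest
   shortest path (double-sweep Dijkstra). Two refinements follow: a few
   midpoint-averaging passes (identity on exactly straight uniform chains,
   so a one-voxel-thick straight mask yields exactly its voxel centres)
   remove lattice zigzag, and centroid recentring perpendicular to the
   local tangent damps the low-frequency radial wander of thinning
   skeletons. Because thinning retracts from tube ends by roughly one
   radius, the path is then regrown in short tangent steps, recentring each
   new endpoint, until it reaches the mask boundary. The path is ordered
   proximal-first, the proximal end being the one with the larger inscribed
   radius (coronary branches taper distally).
2. **Inscribed radius**: the spacing-aware Euclidean distance from a
   centreline point to the nearest background voxel centre, computed
   exactly against the background shell rather than interpolated from the
   grid distance transform — interpolation systematically underestimates
   the radius for tubes oblique to the lattice.
3. **Mean diameter**: twice the arithmetic mean of the radii, excluding
   points within one maximal radius of either path end, where the inscribed
   sphere is limited by the tube's end cap rather than its wall.
4. **Mean absolute curvature**: the path is resampled to a uniform
   arc-length step (the minimum voxel dimension when called from the
   pipeline), coordinates are Gaussian-smoothed with σ = 1.0 mm (default;
   suppresses voxelisation noise that otherwise dominates |κ|), and
   κ = |x′×x″|/|x′|³ is evaluated by central differences. Samples within
   ~3σ of either end are excluded from the average because the truncated
   smoothing kernel and one-sided differences bias κ there.

Verified recovery on analytic phantoms: cylinder diameters within one voxel
across radii 1–4 mm and spacings 0.3–0.625 mm; arc curvature within 5% at
radius 10 mm; helix curvature within 10% of κ = r/(r²+c²); straight tubes
below 10⁻³ mm⁻¹. Absolute curvature values depend on the smoothing width, so
cross-study curvature comparisons are meaningful in trend rather than
magnitude.

## Cohort statistics

Pearson correlations use the sample formula with two-sided p-values from
the t transform on n−2 degrees of freedom. Welch's t-test uses sample
(ddof = 1) variances and Welch–Satterthwaite degrees of freedom, two-sided.
Calcium scores stratify as 0 → none, 1–99 → low, 100–399 → moderate,
≥400 → high; non-integer scores in (0,1) count as low (any non-zero burden
is calcified). The analysis layer reports raw p-values with significance
flagged at p < 0.05 and **no multiplicity correction** — the audit is
exploratory, and corrected and uncorrected readers can both work from the
raw values. Cells with fewer than 3 observations per group, or degenerate
variance (for example when truth is evaluated against itself and every DSC
is exactly 1), are reported as not-estimable rather than dropped or raised,
so small strata remain auditable.

## Synthetic phantoms

Each phantom is a stylised six-branch coronary tree in a 48 mm³ field of
view: the left system (LM bifurcating into LAD and LCx arcs, with D1 and
OM1 lines branching off) plus a separate RCA helix, mirroring the two
coronary ostia. Tubes are rasterised around analytic curves (a voxel is
lumen iff its world distance to the axis is at most the local radius);
radii taper distally. HU levels default to lumen 400 / tissue 50 / fat −80,
in the range of contrast-enhanced CTCA. Image degradation is applied in
order: calcified lesions are painted as bright spheres centred on the lumen
wall; isotropic Gaussian blur (in voxels) creates partial-volume softness
and makes lesion HU bleed into lumen and tissue — the blooming artefact;
independent white Gaussian noise of stated SD is added with a fixed seed.
The generator is bit-deterministic given (spec, seed).

The surrogate calcium score weights each inserted lesion's analytic volume
(mm³) by the Agatston density factor of its peak HU (1/2/3/4 for 130–199 /
200–299 / 300–399 / ≥400). It is computed from the known lesions, not by
image thresholding: ground truth is known, and image-based Agatston scoring
is out of scope.

**Pseudo-segmenter.** Real trained networks are out of scope at desk scale,
so segmentations of controllable quality come from a seeded HU-window
connected-component segmenter (three members with jittered lower thresholds
emulate a small model committee for ensembling). Its accuracy naturally
falls with lower contrast, higher noise, stronger blur and near-lesion
blooming, giving the cohort analysis realistic signal. This is a documented
stand-in: every evaluation interface accepts real model outputs (binary
masks or probability maps) unchanged. `degrade_segmentation` offers a
controlled-error alternative (blockwise boundary jitter plus branch
dropout).

**Cohort generation** samples per-case factors from stated ranges: lumen
enhancement 250–500 HU, noise SD 5–25 HU, blur 0.4–1.2 voxels, 0–3 lesions
(radius 0.8–2.0 mm, peak 150–900 HU), with branch-radius scale 0.95–1.15
for male and 0.75–0.95 for female cases — reflecting the smaller artery
diameters of female patients — and ±12% shape jitter on arc radii and
branch endpoints so curvature varies across cases. These ranges are the
study conditions of the synthetic experiments; they were chosen once as
plausible CTCA values. Default problem sizes are 96³ voxels at 0.5 mm for
cohort runs and 64³ at 0.75 mm for quick checks, with 40-case cohorts for
the headline correlation analyses.

**What the phantoms do not emulate:** real cardiac anatomy and its
population variability, motion artefacts, beam hardening and reconstruction
physics (noise is white, not sinogram-shaped), stents or bypass grafts, and
the failure modes of actual neural networks. Passing the closed-loop tests
therefore shows that the *measurement pipeline* is correct and directionally
sensitive — not that any particular clinical segmenter behaves this way.

## Numerical and degenerate-input conventions

- Alignment between image and mask grids is enforced to 1e-4 relative
  tolerance on spacing and affine; mismatches name the differing attribute.
- Region statistics accumulate in float64 even when volumes are stored as
  float32.
- Empty artery masks, masks filling the whole volume, zero ring SD, empty
  reference branches, sub-minimum group sizes and negative calcium scores
  all raise informative errors at the operation level; the cohort runner
  converts per-case failures into logged skips (and per-branch failures
  into missing fields) so one corrupt case cannot silently bias or abort a
  cohort.
- `run_pipeline` output is byte-identical across re-runs of the same config
  and seed; timestamps appear only in logs.

## Known limitations

- Thinning-based centrelines are reliable for tubular, non-touching
  branches; heavily fused or cavernous masks would need a mesh- or
  flux-based method.
- Curvature magnitudes depend on the smoothing scale (σ = 1 mm default).
- The per-branch attribution rule charges all false-positive voxels to the
  nearest branch, which can slightly deflate a small branch's DSC when a
  neighbouring large branch is oversegmented.
- The pseudo-segmenter is threshold-based; it cannot reproduce semantic
  failure modes (e.g. confusing veins for arteries).
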