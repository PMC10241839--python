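# Methods

## The pipeline

`lesionloc` localises traumatic brain injury (TBI) lesions on head CT by
atlas mapping. Given a native CT scan and a voxelwise lesion segmentation
with four classes — intraparenchymal haemorrhage (IPH), extra-axial
haemorrhage (EAH), perilesional oedema, and intraventricular haemorrhage
(IVH) — the per-scan pipeline is:

1. **Register.** The preprocessed scan is registered to a population CT
   template with a 12-degree-of-freedom affine transform (translation,
   rotation, anisotropic scale, shear), maximising an intensity similarity
   metric. The registration is repeated from several perturbed
   initialisations ("seeds", default four) and the result with the highest
   similarity is kept.
2. **Invert and project.** The inverse of the winning affine maps the
   template-space anatomical parcellation (31 regions by default) into
   native patient space with nearest-neighbour interpolation.
3. **Quantify.** The overlap between projected regions and the segmentation
   yields a per-region × per-class volume table in mL, together with region
   volumes, the whole-brain volume, and per-class totals.

Optionally, the segmentation can be pushed through the template's non-linear
mapping into MNI space for population-level analysis on a common grid.

### Coordinate and transform conventions

Images are numpy arrays indexed `(i, j, k)` with a 4×4 voxel-to-world affine
in mm (RAS, enforced at load). Transforms follow the resampling convention:
a transform maps points of the *target* (fixed) grid's world frame into the
*moving* image's world frame, so `register(moving=scan, fixed=template)`
returns the template→native mapping and the parcellation is projected with
exactly that transform (the "inverse" of the scan→template alignment).
Deformation fields are dense displacement images `x → x + d(x)`; their
numerical inverse is computed by fixed-point iteration (tolerance 0.1 voxel,
≤50 iterations), after inverting any affine part exactly.

## Intensity preprocessing

CT volumes are clipped to a soft-tissue window, default **[0, 100] HU**, and
rescaled to [0, 1]. This suppresses bone (≫100 HU) and air (−1000 HU) so the
correlation metric is driven by brain/CSF contrast rather than the
dominating skull edge. The window is configurable. Non-finite voxels are
replaced by the window minimum at load and counted in a logged warning.
Out-of-field voxels in intensity resampling are filled with the window
minimum; label resampling always uses nearest-neighbour and fills with
background 0.

## Similarity metric (SM) and registration

The SM is the **Pearson correlation coefficient** of intensities, computed
over a mask (default: voxels where the fixed image exceeds 0.01 after
preprocessing, i.e. the head). It is the registration objective for CT-to-CT
stages, the per-scan quality proxy reported to QC, and the quantity the
multi-seed selection maximises. Properties used by the tests: symmetry,
invariance under positive linear rescaling, and the [−1, 1] range; zero
variance in the mask yields a defined result of 0 with a warning.

Registration is SimpleITK's `ImageRegistrationMethod`: regular-step gradient
descent with physical-shift parameter scaling, a 4-level multi-resolution
pyramid (8×/4×/2×/1× shrink, smoothing σ = 3/2/1/0 voxels), dense metric
sampling, single-threaded metric evaluation, and a budget of 200 iterations
per level. Both the extra coarse level and the generous budget exist for
capture range: with a 3-level pyramid or 100 iterations, a small fraction
of strongly rotated, strongly scaled poses converged to a secondary
optimum several voxels from the truth. The
initial transform aligns intensity centres of mass; seed *k* > 0 perturbs it
by rotations up to ±10°, translations up to ±10 mm and log-scales up to
±0.1, drawn from `default_rng(k)`, so results are deterministic given
(moving, fixed, seed). A failed optimisation returns the identity transform
flagged unsuccessful with its (poor) SM recorded, so downstream QC catches
it rather than the pipeline aborting.

**Cross-modality stages use mutual information.** The first template
iteration (CT scans versus an MR-based target) and the template→MNI mapping
register images whose intensities are not linearly related: in the windowed
CT the skull is the brightest tissue, in T1-like images the darkest, so the
pooled Pearson correlation of two *aligned* images is strongly negative and
maximising it drives the optimiser away from alignment. These stages
therefore optimise Mattes mutual information (32 bins); the reported SM
remains the Pearson correlation throughout, which is why provenance
records a negative mean similarity for the cross-modality iteration.

Deformable registration is a free-form B-spline with control-point spacing
of 8 voxels (the coarse grid is the smoothness constraint), optimised with
L-BFGS-B over a 4×/2× pyramid and converted to a dense displacement field on
the fixed grid. With the correlation metric, if the optimised field does not
improve the masked SM the zero field is returned, so deformable refinement
never degrades similarity; phantom fields show positive Jacobian
determinants everywhere (no folding).

## Template construction

The template is built from non-lesioned scans by iterated
register-resample-average, default schedule **four affine then three
deformable iterations**. The first target is the cross-modality MR-like
template; each subsequent target is the voxelwise mean of the registered
scans, so the target sharpens as alignment improves. Affine iterations
re-register from scratch (`n_seeds` configurable, default 1 here — the
multi-seed robustness device is aimed at pathological patient scans;
template cohorts are non-lesioned and well initialised); deformable
iterations compose a refinement with the scan's last affine and resample
the original scan through the composition in a single interpolation. Scans
failing registration in an iteration are excluded from that iteration's
average and logged. Averaging is done on preprocessed [0, 1] intensities
and the template is stored on that scale: it is only ever a registration
target and label carrier. Provenance records the per-iteration mean SM and
a sharpness index (mean gradient magnitude per mm within the head mask).
On phantom cohorts the mean SM rises from the (negative) cross-modality
first iteration to ≈0.98 and the sharpness index increases monotonically;
consecutive late iterations can jitter in the fourth decimal, so
convergence is asserted as first-to-last improvement plus non-regression,
not strict stepwise monotonicity.

## Atlas propagation

The template is registered to the MNI-space image (affine + deformable, both
mutual-information-driven), the two stages are composed into one dense
template→MNI displacement field, and its numerical inverse is computed on
the MNI grid. The MNI parcellation is pulled onto the template grid with
nearest-neighbour interpolation (labels are never invented) and then
**dilated by 10 mm** (configurable): every background voxel within the
margin receives the label of its Euclidean-nearest labelled voxel. Dilation
exists because patient mapping is affine-only — in patients with larger
heads the undilated atlas would miss peripheral lesion voxels. Dilated
voxels count toward lesion assignment but not toward brain volume, which is
restricted to the pre-dilation brain mask; lesion voxels on background even
after dilation are reported as "unassigned", never dropped, which makes the
table's conservation law exact: per class,
Σ regions + unassigned = whole-brain total.

## Quality control

Three per-scan flags, a scan being flagged overall iff any is set:

- **SM flag** — SM strictly below the threshold, default **0.65**.
- **Region-outlier flag** — per region, the cohort distribution of
  projected region volume is summarised by Tukey fences (quartiles ±
  1.5×IQR); a scan is flagged iff strictly more than **5** of its regions
  are outliers. Cohorts below 5 scans give no flags, with a warning.
- **IVH flag** — IVH volume localised outside the ventricle labels
  (including unassigned IVH) strictly above **1 mL** is anatomically
  implausible and flagged.

All three boundaries are strict inequalities by design ("below", "more
than", "higher than"). The SM's discriminative power against expert visual
scores (1–5; acceptable ≥ 3, or ≥ 4 for ventricle-sensitive studies, both
exposed) is measured as the tie-aware Mann–Whitney AUC.

## Population analysis

Per-region prevalence counts the subjects whose per-region, per-class volume
strictly exceeds a threshold; the minimum defensible threshold is **0.1 mL**
(affine mapping has no voxel-level accuracy, smaller volumes are likely
misalignment noise) and is enforced unless explicitly overridden. Voxelwise
prevalence maps count subjects per voxel over MNI-space segmentations.
Outcome stratification groups subjects by the Extended Glasgow Outcome
Scale: good = GOSE > 7, poor = GOSE < 7, with GOSE = 7 excluded under the
literal strict reading (a flag switches to the conventional ≥7/<7
dichotomy); QC-flagged scans and subjects without outcomes are excluded.
When a subject has several scans the first supplied table is used.

## The phantom test bed

Clinical CT and expert ratings are not distributable, so correctness is
demonstrated on a synthetic head phantom with exactly known geometry: an
ellipsoidal brain (semi-axes 40×50×35 mm) inside a 6 mm ellipsoidal skull
shell, two ellipsoidal lateral ventricles, tissue intensities air −1000 /
CSF 5 / brain 35 / skull 700 HU, Gaussian noise (σ = 5 HU), on a 64³ grid at
2 mm isotropic spacing. Two deliberate departures from a plain ellipsoid
matter for registration realism:

- a deterministic low-frequency sinusoidal **parenchymal texture**
  (amplitude 15 HU, wavelengths ≈ 20–40 mm) stands in for anatomical
  structure; without it the phantom is rotationally near-degenerate and no
  intensity metric can pin down rotation and scale the way real anatomy
  does;
- posed cohort scans are **rendered analytically** at their pose (the
  geometry is evaluated at transformed coordinates) rather than resampled,
  because interpolating the 1700 HU skull edge through the CT window
  creates edge artefacts that measurably bias the registration optimum.

The parcellation partitions the brain into 31 contiguous sectors: a central
core, 28 ring sectors (2 superior/inferior bands × 14 azimuthal wedges),
and the 2 ventricles, every sector deep enough to contain a sphere of more
than 1 mL. Lesions are spheres with analytically known volumes; their
ground-truth per-region tables are computed by exhaustive voxel counting
against the true parcellation, independent of the pipeline's bookkeeping.
A warped, regridded, MR-contrast remap of the phantom (with the texture
carried through) serves as the cross-modality MNI stand-in; the warp is a
known smooth sinusoid, so label-transfer accuracy can be scored against
ground truth.

**What the phantom does not emulate:** CT physics (beam hardening, partial
volume, metal artefacts), anatomical variability beyond affine poses and
smooth warps, real lesion morphology (classes differ only by placement
convention), and skull-base/posterior-fossa complexity. Passing tests
demonstrate the correctness of the pipeline's geometry, bookkeeping and QC
logic under controlled conditions — not clinical-grade registration
accuracy on pathological scans.

## Numerical choices and degenerate inputs

- Nearest-neighbour for all label resampling; linear for intensities;
  out-of-field fill = background/window minimum.
- Transform serialisation: affines as 4×4 JSON/CSV-able matrices,
  deformation fields as 4D NIfTI vector images (mm).
- Similarity of an empty or constant-intensity mask: 0 with a warning.
- Tie-break in multi-seed selection: the lowest seed index wins exact ties.
- Registration failure: identity transform, `success=False`, SM recorded.
- Degenerate QC cohorts (<5 scans): outlier flags undefined → False with a
  warning. AUC with a single class: undefined → `None` with a warning.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); registrations are single-threaded and
  bitwise reproducible given their seed.

## Problem sizes

Default phantom studies: 20 scans for affine recovery, 10 for template
construction (full 4+3 schedule), 3 end-to-end lesioned scans, 21-scan QC
cohorts, 100 AUC sets, 15-subject prevalence cohorts — sizes chosen so the
whole suite runs on a single CPU desk machine in well under half an hour
while still exercising every pipeline stage at cohort scale.

## Known limitations

- Patient mapping is affine-only (as designed): voxel-level localisation is
  out of reach and boundary regions trade volume with their neighbours;
  the 0.1 mL prevalence floor and the QC rules exist precisely for this.
- The region-outlier rule assumes a cohort processed together and pools the
  distribution per region across scans.
- The cross-modality first template iteration depends on a reasonable MR
  target; grossly different fields of view would need manual cropping.
- The integer class encoding {1: IPH, 2: EAH, 3: oedema, 4: IVH} is a
  convention, remappable via `class_map`.
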