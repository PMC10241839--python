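# lesionloc

Atlas-based localisation and per-region quantification of traumatic brain
injury (TBI) lesions on head CT.

Voxelwise lesion segmentation tools tell you *how much* haemorrhage or
oedema a patient has, but not *where* it sits anatomically — and lesion
location matters for management, prognosis and population research.
`lesionloc` answers the "where" question for CT: it registers each patient
scan to a population CT template, projects an anatomical parcellation back
into patient space through the inverse transform, and measures the overlap
between the projected regions and the lesion segmentation. The output for
each scan is a table of lesion volume (mL) per brain region and per lesion
class — intraparenchymal haemorrhage (IPH), extra-axial haemorrhage (EAH),
perilesional oedema, intraventricular haemorrhage (IVH) — plus region
volumes, whole-brain volume, and automatic quality-control (QC) flags that
catch failed atlas mappings without any manual inspection.

The core quantities, in the field's usual notation:

- **SM** — the similarity metric, the Pearson correlation coefficient of
  (windowed, [0,1]-rescaled) image intensities over the head mask after
  registration. Each scan is registered with four random initialisation
  seeds and the highest-SM result is kept; SM < 0.65 flags a sub-optimal
  mapping.
- **Per-region lesion load** — for region *r* and class *c*,
  `V(r, c) = v · |{x : P(x) = r ∧ S(x) = c}|`, where `P` is the projected
  parcellation, `S` the segmentation and `v` the voxel volume in mL. Lesion
  voxels outside every region are reported as "unassigned", so per class
  `Σ_r V(r, c) + V(unassigned, c)` equals the whole-brain total exactly.
- **QC flags** — SM below threshold; more than five regions whose projected
  volumes are Tukey-fence outliers of the cohort distribution; more than
  1 mL of IVH localised outside the ventricle labels (anatomically
  implausible).
- **Prevalence** — per region and class, the number of subjects with
  `V(r, c)` above a threshold (minimum 0.1 mL).

The package also contains the machinery to *build* the atlas: iterative
population-template construction (four affine + three deformable
register-average iterations starting from an MR-based target) and
propagation of an MNI-space parcellation onto the template via non-linear
registration, with label dilation beyond the skull so that affine-only
patient mapping never loses peripheral lesion voxels.

Because clinical CT cannot ship with a repository, a first-class phantom
module generates synthetic head scans (ellipsoidal brain/skull/ventricles,
parenchymal texture, 31-region geometric parcellation, spherical lesions of
exactly known volume, cohorts at known random poses) on which every stage of
the pipeline is validated against analytic ground truth.

## Worked example

Localise a synthetic lesion with a known volume and position:

```python
import numpy as np
from lesionloc import (PhantomSpec, make_phantom, inject_lesion,
                       ct_preprocess, localise, TemplateBundle)
from lesionloc.atlas import dilate_parcellation
from lesionloc.phantom import deepest_point, random_affine, ventricle_ids

spec = PhantomSpec()                      # 64³ head phantom, 2 mm voxels
scan, parc, mask = make_phantom(spec)     # canonical phantom = our template
bundle = TemplateBundle(template=ct_preprocess(scan),
                        parcellation=dilate_parcellation(parc, 10.0),
                        brain_mask=mask, ventricle_ids=ventricle_ids(parc))

# a patient: the same head at an unknown pose, with a 2.1 mL EAH in region 9
pose = random_affine(np.random.default_rng(5), 12.0, 8.0, (0.92, 1.08))
patient, patient_parc, _ = make_phantom(spec, pose=pose)
center, depth = deepest_point(patient_parc.data == 9, patient_parc.affine)
patient, seg, truth = inject_lesion(patient, patient_parc, class_id=2,
                                    center_mm=center, radius_mm=depth - 0.5)

table, reg = localise(patient, seg, bundle, n_seeds=4, scan_id="example")
print(f"SM = {reg.similarity:.3f} (seed {reg.seed})")
print(f"true EAH in region 9:      {truth[truth.region_id == 9].eah_ml.iloc[0]:.3f} mL")
print(f"estimated EAH in region 9: {table.row(9).eah_ml:.3f} mL")
print(f"whole-brain EAH total:     {table.row(-1).eah_ml:.3f} mL")
```

Output:

```
SM = 0.916 (seed 3)
true EAH in region 9:      2.008 mL
estimated EAH in region 9: 1.984 mL
whole-brain EAH total:     2.008 mL
```

The multi-seed registration recovered the pose (seed 3 won with SM 0.92),
the lesion is attributed to the correct region with a 1.2% volume error,
and the whole-brain total equals the ground-truth lesion volume exactly —
the conservation property guarantees region rows plus "unassigned" always
sum to the totals.

The same stages are available on the command line (`lesionloc phantom`,
`build-template`, `propagate-atlas`, `localise`, `qc`, `prevalence`,
`stratify`); see `lesionloc --help`.

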