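# rcmorph

Quantitative anatomy of **Rosenthal's canal** (RC) — the helical bony
channel inside the cochlear modiolus that houses the ~30,000–35,000
spiral-ganglion neuron cell bodies — and **surgical access planning to it
through the round-window (RW) membrane**, for labelled 3-D temporal-bone
volumes.

The package is aimed at researchers working on inner-ear therapeutics
delivery who need reproducible canal morphometry (centerline length,
station diameters, volumes) and a probability map of which part of the RW
membrane to penetrate to reach the canal safely.  Because the synchrotron
phase-contrast scans behind this kind of study are not public, `rcmorph`
includes a parametric synthetic temporal-bone generator with exact ground
truth; the entire measurement and planning pipeline is validated against
it and against closed-form phantoms.

## What it computes

Given a label map (NRRD or NIfTI, isotropic spacing, fixed label scheme:
bone 1, perilymph 2, canal 3, RW membrane 4, artery 5, stapedius 6,
modiolar CSF 7):

* **Morphometry** — canal centerline by 3-D thinning with end-cap
  correction; arc length *L*; modiolar-axis fit; diameters *d(θ)* at the
  0°/45°/90° cochlear-angle stations from the Euclidean distance transform
  (maximal inscribed sphere, 2·EDT − Δx/2); label volumes (exact voxel
  counts), including the ~15 mm³ central nerve-exit space; bony-shell
  minimum thickness and dehiscence.
* **Access planning** — least-squares RW plane fit; a size-adjusted 4×4
  *dynamic grid* (rows A–D superior→inferior, columns 1–4
  anterior→posterior); per cell, a trephine capsule (radius 0.2 mm, depth
  limit 4 mm) swept along the inward membrane normal; per-cohort hit
  frequencies f = hits / evaluable, artery-collision safety flags,
  stapedius-occluded cells reported as *not evaluable*; selected cells are
  those with f ≥ 0.8, safe, and evaluable in every specimen.
* **Cohort report** — per-specimen table rows with Average and sample-SD
  (n−1) summary rows, heat-map CSV and figure.  A packaged fixture carries
  the published ten-bone reference table for exact closure checks
  (mean length 14.568 mm, SD 0.36058, range 14.02–15.08 mm).

## Worked example

```python
from rcmorph.pipeline import run_study

study = run_study(n=10, seed=1, spacing=0.018)

print(f"measured canal length: {study.table.average_row['rc_length']:.3f} mm")
print(f"selected cells: {sorted(study.heatmap.selected)}")
print(f"depth to canal, median: {study.depths['median']:.2f} mm")
```

prints (about a minute per specimen on one core):

```
measured canal length: 14.690 mm
selected cells: ['A2', 'B2']
depth to canal, median: 3.53 mm
```

The measured mean length sits within a fraction of a percent of the
cohort's ground-truth lengths (drawn from Normal(14.568, 0.36058) mm); the
selected cells are confined to the superior half of the membrane, with the
anterior column (B1/C1) excluded as unsafe because the vestibulocochlear
artery crosses those trajectories, and D1 not evaluable under the
stapedius; the canal lies 3–4 mm deep to the membrane.

The same pipeline is available as a CLI:

```sh
rcmorph generate-cohort --n 10 --seed 1 --spacing 0.018 --out-dir cohort/
rcmorph measure --in cohort/specimen_00.nrrd --out rec.csv
rcmorph plan-access --cohort-dir cohort/ --out heatmap.csv
rcmorph report --records records.csv --out report/
```

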