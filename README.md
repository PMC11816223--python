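# fivedct

Model-based respiratory-phase CT ("5DCT") for radiotherapy simulation
imaging: fit a per-voxel breathing-motion model to deformable-registration
displacements and a bellows surrogate, then reconstruct artifact-free
respiratory phase images from fast-helical free-breathing CT — together with
the workflow's QA measures and a synthetic deforming-thorax simulator so the
whole pipeline is testable without clinical data.

## The problem

Conventional 4DCT sorts free-breathing scan data into phase bins; when the
patient breathes irregularly, data land in the wrong bins and the images show
sorting artifacts that obscure tumor position. The model-based alternative
implemented here avoids binning entirely. A session acquires N fast-helical
free-breathing CT volumes (default N = 25, the first a high-dose reference)
while an abdominal bellows records a respiratory surrogate. Deformable image
registration (DIR) measures per-voxel displacement between the reference and
every other scan, and the displacements are fitted to the surrogate.

## The model

Each voxel follows a linear motion model in breathing amplitude *A* and
breathing rate *Ȧ*:

    X = X₀ + α·A + β·Ȧ

where X₀ is the voxel's position in the reference image, α (mm per a.u.)
scales amplitude and β (mm per a.u./s) scales rate, producing hysteresis
between inhalation and exhalation. α and β are estimated per voxel and axis
by ordinary least squares with no intercept on amplitude/rate deltas from the
reference scan's own slice tags. Voxels that do not move (spine, bone) get
α = β = 0. Once fitted, the model synthesizes a CT volume at *any* (A, Ȧ):
the predicted displacement field is inverted by damped fixed-point iteration
and the reference volume is pulled back through the inverse, so all
Hounsfield units come from the reference scan.

Eight phase images are generated at the 0, 25, 50, 75 and 100 % amplitudes
of the outlier-trimmed [P5, P95] surrogate range during exhalation and
75, 50, 25 % during inhalation, with rates read from a representative breath
built from the patient's own trace. Voxel-wise maxima give the MIP (over the
8 phases) and the MEGA-MIP (over all N scans) used for ITV contouring and as
a motion-envelope cross-check.

QA outputs mirror the clinical report: scan on/off window detection, scan
range validation, head-first/foot-first sub-millimeter shift correction,
bellows drift correction against abdominal surface heights, breath
segmentation and the representative breath, green/magenta DIR overlays,
model-fit residual statistics (mean / SD / 95th percentile over the lungs,
1 mm histogram, residual MIPs) and original-scan reconstructions. The
statistics module houses the grading/usability data model with Spearman
correlations (Fisher-z CIs), multiple linear regression with standardized
coefficients and adjusted R², and usability-group accounting.

## Worked example

```python
from fivedct import make_default_phantom, WaveformSpec, simulate_session, run_workflow

phantom = make_default_phantom(grid_shape=(48, 48, 32), voxel_size=(5.0, 5.0, 3.75))
session = simulate_session(phantom, WaveformSpec(seed=1))
result = run_workflow(session, tag_source="surrogate")
```

This simulates a 25-scan session of a breathing thorax phantom (bellows
drift 0.005 a.u./s, noise 0.01 a.u.), processes the surrogate, fits the
model from ground-truth deformation fields and reconstructs the phase set.
Printing the key results gives:

```
scans: 25  reference: scan 0
deformation fields: 24
bellows drift slope estimate: +0.0050 a.u./s
bellows/abdomen correlation: 0.9992
amplitude percentiles  P5=-0.486  P85=0.427  P95=0.526 a.u.
phase targets:
   0ex: A=-0.486 a.u.  Adot=+0.000 a.u./s
  25ex: A=-0.233 a.u.  Adot=-0.602 a.u./s
  50ex: A=+0.020 a.u.  Adot=-0.802 a.u./s
  75ex: A=+0.273 a.u.  Adot=-0.859 a.u./s
   100: A=+0.526 a.u.  Adot=+0.000 a.u./s
  75in: A=+0.273 a.u.  Adot=+0.629 a.u./s
  50in: A=+0.020 a.u.  Adot=+0.815 a.u./s
  25in: A=-0.233 a.u.  Adot=+0.588 a.u./s
model fit residuals over 5826 lung voxels x 24 scans:
  mean=0.027 mm  sd=0.030 mm  p95=0.087 mm
```

The drift estimate matches the injected 0.005 a.u./s; the exhalation phases
carry negative rates and the inhalation phases positive ones; and with
exact deformation fields the only residual error is what the surrogate
processing itself introduces (drift-correction and derivative estimation),
here well under a tenth of a millimeter.

The same pipeline is available from the shell:

```
fivedct simulate --out session/ --seed 1
fivedct reconstruct --session session/ --out recon/
fivedct qa --session session/ --out qa/
fivedct stats --grades grades.csv --out stats.json
```

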