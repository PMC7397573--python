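# kbplan

Knowledge-based IMRT dose-objective prediction for locally advanced
nasopharyngeal carcinoma (NPC) planning.

Inverse IMRT planning for NPC is a slow trial-and-error loop: a planner
repeatedly adjusts the tunable dose levels of a fixed objective template
until target coverage and organ-at-risk (OAR) sparing are balanced.
`kbplan` implements a knowledge-based alternative: the *geometry* of a
new patient, summarised by overlap volume histograms (OVH) and target
volume histograms (TVH), is mapped by a shallow neural-network ensemble
directly to the patient-specific dose objectives a planner would have
converged to — so a plan can be optimised in a single pass.  The
package is aimed at medical-physics researchers studying automated
planning; it deliberately stops at the treatment-planning-system
boundary and exports objectives as neutral text files.

## Model

For each OAR *s* and target *T*, the OVH is the curve

    OVH_s,T(t) = |s ∩ T_t| / |s|,

where *T_t* is the target uniformly expanded (t > 0) or contracted
(t < 0) by |t| in physical millimetres (Euclidean distance transform,
anisotropic voxel spacing respected).  The TVH is the analogous relative
volume |T_t| / |T| of a target itself.  Twenty OVH pairs and five TVH
targets, each sampled at 11 distances, give a 275-value geometric
descriptor per patient.

A fully connected 275–184–21 network (logistic hidden units, linear
output) maps the min-max-normalised descriptor to 21 normalised dose
objectives; it is trained by full-batch gradient descent on the mean
squared error at learning rate 0.02 for 2500 iterations.  The knowledge
library is split chronologically into 5 equal folds; each fold model
trains on the other 4 folds (scalers fitted on those folds only) and
validates on its own.  The deployed prediction is the arithmetic mean,
in cGy, of the five fold predictions.

The 21 predicted doses are substituted into a fixed clinical objective
template: MinDVH/MaxDVH/UniformDose entries per ROI with preset volume
points and weights, fixed constants (6100 and 6600 cGy caps), and
derived relations (each primary MaxDVH = its MinDVH + 100 cGy;
UniformDose = MinDVH + 50 cGy, configurable to 75).  Plan quality is
assessed with D_x, V_x, D_xcc, Dmax, the conformity index
CI = (A/|PTV|)·(A/B) and the homogeneity index HI = D5/D95, against the
institutional protocol criteria.

Because no public NPC structure-set cohort exists, the package ships a
first-class synthetic module: virtual head-and-neck patients (nested
GTV/CTV targets, bilateral nodal targets, ten OARs, body contour) with
randomised geometry, plus a known linear feature→objective ground truth
so that every stage — geometry, learning, resolution, evaluation — is
testable end to end.

## Worked example

```python
import numpy as np
from kbplan.model import TrainConfig, cross_validate, predict
from kbplan.objectives import resolve_objectives, clamp_objectives
from kbplan.synthetic import (GeometryParams, generate_library,
                              generate_patient, extract_features)

# build a 20-patient synthetic knowledge library (full geometric pipeline)
library, _ = generate_library(20, seed=42)
print(f"library: {library.n_patients} patients x {library.X.shape[1]} features")

# train the chronological 5-fold ensemble at the default settings
ensemble = cross_validate(library, TrainConfig(), k=5)
print("validation MSE per fold:",
      ", ".join(f"{f.validation_loss:.4f}" for f in ensemble.folds))

# predict dose objectives for a new virtual patient
patient = generate_patient(GeometryParams(seed=777))
features = extract_features(patient)
doses_cGy = predict(ensemble, features)
objectives = clamp_objectives(resolve_objectives(doses_cGy, patient_id="demo"))
for row in objectives.resolved[:5]:
    print(f"{row.roi:<10} {row.objective_type:<12} {row.dose_cGy:8.1f} cGy")
```

prints

```
library: 20 patients x 275 features
validation MSE per fold: 0.0429, 0.0705, 0.1195, 0.0821, 0.1037
GTV_T_P    MinDVH         6956.2 cGy
GTV_T_P    MaxDVH         7056.2 cGy
GTV_T_P    UniformDose    7006.2 cGy
CTV1_GTV   MinDVH         6107.5 cGy
CTV1_GTV   MaxDVH         6956.2 cGy
```

The per-fold validation MSE is in normalised units (a 20-patient toy
library generalises worse than the default 115-patient one).  The
predicted primary MinDVH lands near the 6996 cGy prescription, and the
template relations are visible directly: the MaxDVH sits exactly
100 cGy above the MinDVH, the UniformDose 50 cGy above it, and the
CTV1_GTV avoidance MaxDVH equals the primary MinDVH.

The same workflow is available from the shell:

```bash
kbplan simulate --patients 115 --seed 1 --out lib/
kbplan train --features lib/features.csv --objectives lib/objectives.csv \
             --folds 5 --lr 0.02 --iters 2500 --seed 2016 --out model.json
kbplan make-phantom --seed 7 --out patient/
kbplan autoplan --structures patient/structures --model model.json --out plan/
kbplan evaluate --dose patient/dose.nii.gz --structures patient/structures --out report/
```

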