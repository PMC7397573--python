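# Methods

## Geometry engine

Structures are boolean masks on a shared regular grid with anisotropic
physical spacing (default 2×2×3 mm; head-and-neck CTs are commonly
acquired at 3 mm slice spacing).  A voxel belongs to a structure by its
centre point.  Uniform expansion by *d* mm is implemented as
thresholding the Euclidean distance transform of the mask's complement
(`scipy.ndimage.distance_transform_edt` with the physical spacing as
sampling): a voxel is in the expansion iff its centre lies within *d*
of some structure-voxel centre.  Contraction thresholds the interior
distance transform and keeps voxels strictly deeper than *d*.  These
conventions are shared verbatim by the brute-force per-voxel oracles in
the test suite, so distance-transform and O(N²) pairwise computations
agree *exactly* (no tolerance) on small grids.

Boundary handling: no padding is added; distances are computed within
the grid, and a warning is logged when an expansion or ring is
truncated by the grid edge.  Masks on different grids are never
resampled implicitly — any grid mismatch is an error.

Auxiliary planning structures are derived set-algebraically from the
seven protocol targets: avoidance volumes (e.g. CTV1_GTV = CTV1_P
minus GTV_T_P), the integrated CTV_ALL, and four nested dose-falloff
rings obtained from the 5/10/15/25 mm expansions of CTV_ALL, all
clipped to the body contour.  The body clip is applied after the shell
subtraction; the rings therefore partition the in-body shell region
exactly, which the suite asserts.

## OVH/TVH descriptors

The overlap volume histogram of an OAR against a reference target is
the fraction of the OAR covered by the target morphed by each sampled
signed distance (negative = contraction); the target volume histogram
is the morphed target's volume relative to its original volume.  The
default sampling table contains 20 OVH curves and 5 TVH curves, each
with 11 samples, concatenated in a frozen layout order into a
275-value feature vector.  Distances are configured in cm and converted
to mm with a fixed factor of 10.  If a contraction empties the target
the value is 0, not an error.  TVH values are volume fractions
(TVH(0) = 1 exactly) and are still passed through the feature scaler
like every other input.

Within one patient the two distance fields of each reference target
are computed once and shared across all of its curves; a full
extraction costs ~12 distance transforms (~1.5 s at the default grid).

## Normalisation

Inputs and the 21 objective doses (cGy) are normalised per feature to
[0, 1] by min-max scalers fitted **only on the training folds** of each
cross-validation model; degenerate features (max = min) map to 0.
Min-max was chosen over z-scoring because it is reversible, keeps the
sigmoid network's inputs in a bounded box, and is the conventional
choice for shallow sigmoid regressors.  Outputs are normalised
per-objective (not jointly).  At prediction time, features outside the
trained range are clamped to [0, 1] with a logged warning rather than
extrapolated.

## Network and training

One fold model is a fully connected 275–184–21 network: logistic
sigmoid hidden layer, linear output layer (targets are normalised, so
an unbounded output head is appropriate).  Weights are initialised
scaled-uniform (Glorot-style, `init_scale` default 1.0) from a seeded
generator; biases start at zero; the default seed is 2016 and each
fold trains with `seed + fold_index`.

Training is plain full-batch gradient descent — no momentum, no
mini-batches, no regularisation, no early stopping — for exactly 2500
iterations at learning rate 0.02.  The training cost is the per-node
mean squared error summed over the 21 output nodes and averaged over
samples; the `loss` function reported in traces and validation results
is the mean over samples *and* nodes (the two differ by the constant
factor 21 and share their minimiser).  The per-node-sum convention is
the classic one for shallow regression networks and is what makes this
architecture train to convergence within the fixed iteration budget;
with the mean-over-everything gradient the effective step size would be
21× smaller and the same budget would leave the network far from the
minimum.  Training aborts with a `DivergenceError` naming the
iteration if the loss becomes non-finite.

Cross-validation is chronological: patients are kept in treatment-date
order and split into k = 5 contiguous folds (sizes differ by at most
one, larger folds first; 115 patients give five folds of 23).  Each
fold model fits its own scalers on its four training folds, so the
ensemble stores per-fold scalers.  The deployed prediction normalises
with each fold's scaler, predicts, denormalises to cGy, and averages
the five cGy vectors — averaging after denormalisation, because the
folds' output scalers differ.

## Objective template

The template fixes ROI, type (MinDVH / MaxDVH / UniformDose), volume
point and weight for 31 entries; exactly 21 dose values are free and
are the learning targets.  Fixed entries: CTV2_CTV1 MaxDVH 6100 cGy and
the nodal avoidance MaxDVH 6600 cGy.  Derived entries: each gross
target's MaxDVH is its MinDVH + 100 cGy; CTV1_GTV's MaxDVH equals the
primary MinDVH; UniformDose entries sit `uniform_offset_cGy` above
their MinDVH.  The offset is configurable with default 50 cGy and
documented alternative 75 cGy (the clinical convention allows either).
All offsets are interpreted in cGy, consistent with the template's
fixed values.  UniformDose entries carry no volume point or weight.

Predicted free values are clamped into per-index bounds before
resolution — loose envelopes around the prescription levels for
targets and around the protocol dose limits for OARs and rings — to
guard against network extrapolation; clamping is logged and derived
doses are re-resolved from the clamped bases so the internal relations
hold exactly.  Export writes a fixed-column CSV (doses as integers
when integral) and a key-value planning block with pass-through beam /
prescription / optimiser metadata that is never consumed by any
computation here.

## Plan evaluation

D_x is the minimum dose of the hottest x% of a structure, computed on
descending-sorted voxel doses with linear interpolation at the
fractional rank: for N voxels the hottest x% spans f = x/100·N voxels
and D_x is the sorted dose at 0-based fractional index f−1 (clipped to
[0, N−1]).  D_xcc uses the same rule with f = cc / voxel volume.  V_x
is the exact voxel count fraction ≥ x Gy.  CI = (A/|PTV|)·(A/B) with A
the PTV volume at or above prescription and B the total such volume
(CI = 0 when B = 0); HI = D5/D95 (undefined, and an error, when
D95 = 0).  "Spinal cord D1" is the percent-volume metric D at 1%;
D1cc is the absolute-volume metric — both exist as distinct
operations.  Protocol criteria use strict comparators: a measured
value exactly on a threshold fails, and the failure is logged.  The
interpolation convention implies `volume_at_dose(dose_at_volume(x))`
can fall short of x by at most one voxel fraction, which is how the
inverse-consistency property is asserted.

## Synthetic data

The generator emulates what the pipeline consumes, not what a CT
looks like.  A virtual patient is a cylindrical body containing
ellipsoidal gross targets (primary tumour, bilateral nodes) and ten
OARs at anatomically plausible offsets; clinical target volumes are
true Euclidean expansions of the gross volumes (8 mm primary margin +
3 mm setup margin, 5 mm nodal margin by default), so the protocol
nesting holds by construction.  Per-patient randomisation jitters
centres by ±4 mm, radii by ±15% and margins by ±2 mm — enough to make
every OVH/TVH curve vary across a cohort while keeping all structures
inside the body.  A structure thinner than the voxel spacing (possible
for the 3 mm optic nerves on coarse test grids) degenerates to the
voxel nearest its centre rather than vanishing.  Default grid
96×96×64 at 2×2×3 mm; the unit-test suite uses a coarser
48×48×32 / 4×4×6 mm grid with the same physical extent where speed
matters.

Ground-truth objectives are linear in the features: Y = A·x + b, with
optional Gaussian noise (planner variability) and an optional
quadratic term in the leading feature-variation mode (to demonstrate
the hidden layer's extra capacity).  The default mapping couples each
objective to the population's top 10 principal feature-variation
modes, scaled to an objective SD of 150 cGy around nominal dose levels
and centred so the population mean equals those nominal levels.  This
construction has two purposes: it emulates how achievable dose levels
track dominant anatomical variation, and it guarantees the mapping is
well conditioned with respect to the cohort it is applied to — a
sparse random-coefficient mapping can load on near-constant features
or on tiny contrasts between correlated features, which no learner
could recover from 92 training rows.  A `sparse_random_mapping`
factory is retained for such stress cases.  Outputs are clamped to
[0, 8000] cGy, but a well-conditioned mapping never engages the clamp.

The synthetic dose generator assigns each target its prescription
inside itself with exponential falloff exp(−d/8 mm) outside, taking
the voxelwise maximum over targets; default prescriptions sit slightly
above the protocol minima so strict D95-type criteria are satisfiable
on a noiseless grid.  This is a smooth fixture for the evaluation
metrics, not a beam model: it has no penumbra anisotropy, no buildup,
and no inter-structure dose trade-off, so passing criteria on it says
nothing about deliverability.

What passing tests do show: the geometric descriptors are exact (per
the brute-force oracles), the learning machinery recovers a known
well-conditioned linear mapping from realistic-shaped features
(held-out normalised RMSE < 0.05 at the fixed training budget), and
the template/evaluation logic matches its stated conventions.  What
they cannot show: that real planner behaviour is linear in OVH/TVH
features, that the clinical feature distribution resembles the
synthetic one, or anything about dose deliverability on a real TPS.

## Problem sizes

The default study configuration is a 115-patient knowledge library and
a 25-patient test library, generated as one 140-patient chronological
cohort.  The acceptance script runs exactly this configuration (~4 min
on one CPU); the test suite shares a single session-scoped 115-patient
library between the fold-structure and learning checks and uses
12–20-patient coarse-grid libraries elsewhere.

## Known limitations

* DICOM RT-STRUCT rasterisation is out of scope; structures enter as
  NIfTI masks (per-structure files or a label map + YAML name table).
* The exported planning block is a neutral schema; no TPS integration
  or inverse optimisation is performed.
* Sub-voxel (marching-surface) OVH is not implemented; curves are
  voxel-exact, so very small structures quantise visibly.
* The activation, optimiser variant, initialisation and normalisation
  scheme are package conventions chosen for this architecture class;
  they are documented above rather than inherited from any external
  reference implementation.
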