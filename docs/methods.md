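# Methods

## Coordinate and measurement conventions

All world coordinates are millimetres in a fixed anatomical frame:
x = left–right, y = posterior–anterior, z = inferior–superior. NIfTI input
is reoriented to the closest canonical RAS orientation on read, so "x
width" and "z length" are unambiguous everywhere downstream.

The coronal reference planes pass through the AC and PC landmarks with
normal along the AC–PC line. Landmarks are required inputs (sidecar JSON);
no automatic detection is attempted. Whether a clinical workstation
reformats along the AC–PC line or scanner axes after manual alignment is
generally unknowable from a published protocol; the landmark-based
construction is this package's fixed choice. Slices are resampled
nearest-neighbour (labels must stay valid codes) onto the volume's (x, z)
grid; slab thickness defaults to one voxel and thicker slabs take the
per-pixel majority label.

A linear extent is measured caliper-style: `(last − first + 1) × spacing`
over the occupied voxels, boundary to boundary, bridging interior gaps.
This mirrors manual caliper placement and is unbiased for a chord to first
order (the half-voxel overhangs on each side compensate the interior
offsets of the voxel centres).

## The six indices

* **Evans index** — frontal horns are delimited as lateral-ventricle
  voxels strictly anterior to the AC coronal plane (a deterministic,
  landmark-driven proxy for the foramen-of-Monro boundary, which labeled
  volumes do not localize). Per axial slice the horn x-extent is measured;
  the maximal slice supplies the numerator and the intracranial x-extent
  of that same slice the denominator.
* **z-Evans index** — on the AC coronal slice, numerator = maximal
  ventricular z-extent over columns; denominator = intracranial z-extent
  at the midline column (x of the AC).
* **Callosal angle** — on the PC coronal slice, each side's roof is the
  set of topmost ventricle pixels per column; a least-squares line is
  fitted per side and the angle between the lines is measured below their
  intersection (steep DESH roofs give small angles; flat collinear roofs
  give 180°). Least squares over all roof columns was preferred to
  two-point apex constructions, which are noise-sensitive.
* **BVR** — per column intersecting the ventricles: ventricular z-extent,
  and parenchymal z-extent strictly above the ventricle's topmost pixel;
  BVR = max(brain above) / max(ventricular extent). The measurement
  direction of the published "maximum width" is not defined; vertical
  (z-column) extents were chosen to match how the reference figures are
  drawn. The printed per-patient BVR values cannot validate this choice
  (their input lengths are not printed), so it is a documented convention,
  not an asserted reproduction.
* **CVR** — convexity-SAS volume over total ventricular volume, from
  voxel-count volumetry; algebraically identical to the ratio of the two
  volume ratios.

Ratios are reported to 3 decimals, the angle to whole degrees, volumes in
mL (0.1 precision in tables, full precision internally).

## Segmentation and volumetry

The brain/CSF split of an intensity volume is a single global threshold
inside the intracranial mask; when no threshold is supplied, Otsu's
bimodal-histogram criterion chooses it (a reproducible default for a step
that clinical workstations leave unspecified; a slice-wise variant was
considered and rejected for determinism). On T2-like contrast CSF is
hyperintense. Volumes are pure voxel counts times voxel volume — no
partial-volume weighting — so TIV = brain + total CSF holds exactly by
construction.

## The DESH phantom

Geometry is ellipsoid-based so every quantity has a continuous-geometry
reference value: concentric-axis cranium and brain ellipsoids (the gap is
the SAS, partitioned into posterior-fossa / Sylvian–basal / convexity
bands by two horizontal planes standing in for the tentorial and
convexity landmarks of a manual partition); two mirrored lateral-ventricle
ellipsoids cut by a flat medial wall (the septum) and a planar roof tilted
θ from vertical, making the callosal angle exactly 2θ; small midline third
and fourth ventricles. Default dimensions give TIV ≈ 1545 mL, brain
≈ 1118 mL, total CSF ≈ 427 mL, Evans ≈ 0.31, z-Evans ≈ 0.41, callosal
angle 63°, BVR ≈ 0.87–0.95, CVR ≈ 0.48 — inside the reported baseline
iNPH ranges. These are targets for the defaults, not assertions.

Two geometric constraints are enforced at validation time. First, the
roof plane must lie at or below the ellipse surface on every surviving
column of the PC slice — otherwise some columns would carry elliptical
tops and the fitted roofs would not recover 2θ; a roof plane of slope
cot θ cannot stay below an ellipse top near the ellipse's inner tip
(vertical tangent), which is exactly why the medial wall exists. Second
(for the randomized specs), the roof is kept below the ventricle-centre
height at the AC slice's outer tip, so the ventricle terminates in a
roof-truncated edge rather than a vertical-tangent sliver; this keeps the
voxel convergence of the BVR numerator first-order regular.

Reference values: ellipsoid and cap volumes are closed form; the doubly
cut lateral ventricle integrates closed-form cross-section areas (ellipse
segments below the roof line) with Simpson quadrature on a dense grid;
index extents maximize closed-form chord functions on dense grids. None
of this touches the voxel grid, so measured-vs-reference comparisons are
genuine discretization tests.

**Resolution tolerances.** Each caliper length carries voxel-scale
uncertainty: the column grid quantizes the domain boundary (the BVR
numerator's supremum sits at the ventricle's lateral edge, where the roof
gradient cot θ ≈ 1.6 converts a sub-voxel offset into ~1 mm), and
max-over-columns selection adds up to another voxel. Recovery tests
therefore trust each length to 2 voxels, giving a ratio tolerance of
`2·dx/numerator + 2·dx/denominator` (floor 2%); the angle to 2°; and
volumes to 2% plus one voxel layer on the planar cut faces (≈ 2 mL at
1 mm — the partition planes cut faces of up to ~2000 mm²). At 1 mm
spacing this works out to roughly 2–6% per ratio; a flat 2% would be
tighter than a single voxel of quantization for every extent under 50 mm
and is not attainable by any estimator under these definitions. Observed
errors across 150 randomized phantoms stay below ~0.7 of these bounds.

The intensity rendering is two-level (parenchyma 100, CSF 300) with
Gaussian noise of SD σ added inside the intracranial mask; σ = 0
reproduces the brain/CSF partition exactly, σ = 20 misclassifies < 1% of
voxels at the default contrast. No cortical folding, partial-volume
effects or MRI physics are modelled: passing phantom tests demonstrates
correctness of the geometry and estimators at voxel resolution, not
robustness to real segmentation error.

The pre/post pair generator shrinks all ventricle z-semi-axes by a factor
and lowers the brain's top surface (bottom fixed) by exactly the freed
volume over the brain's horizontal cross-section, so brain parenchyma and
total CSF are invariant across the pair while the convexity SAS — hence
CVR — strictly increases: the redistribution mechanism, isolated.

## The synthetic cohort

One row per scan. Baselines are truncated normals (truncation at 1% of
the mean keeps everything physiologic while matching mean ± SD reporting;
a lognormal alternative would distort the reported means at these CVs).
The seven compartments share a patient-size factor (SD 0.10, matching the
reported TIV coefficient of variation) plus per-compartment CVs (brain
0.05; ventricle parts 0.35; SAS parts 0.30 — the study reports wide
volume SDs); published tables give no covariances, so a single shared
size factor is the entire correlation structure. Alzheimer comorbidity
(19/54) shifts baseline Evans down by 0.04 and BVR-PC up by 0.18 around
the population mean, reproducing the reported stratum contrast without
changing the overall mean.

Follow-up: the early phase is attended by everyone, mid with probability
28/54, late 16/54; visit days are binomial draws inside each phase window
calibrated to the reported medians (11 / 178 / 559 days). Each attended
scan multiplies every simulated measure by its phase effect — the ratio
of the published phase mean to the baseline mean — times lognormal noise
(σ = 0.06, chosen so the implied early total-CSF change SD is of the
order of the reported ±39 mL). 'Good'-outcome patients (11/54) move half
as far from baseline (attenuation 0.5, a free parameter); 'unsatisfactory'
defaults to 0 as reported. CVR, totals, TIV and volume ratios are always
recomputed from components, never drawn, so conservation identities hold
in every record. Mid/late effect defaults derive from subgroup columns
(n = 28/16) of the published table; per-patient late-phase change rates
are not recoverable from group means and the simulator makes no claim to
reproduce them — its effects are its own parameters, which the recovery
tests verify it round-trips.

## Statistics

Phase binning: day < 0 pre, [0, 30) early, [30, 365] mid, > 365 late. The
reported visit ranges never touch the boundary days, so any consistent
convention is safe; this one is fixed and documented. Changes are stored
as follow-up − baseline (decreases negative); the published methods text
defines absolute change with the opposite sign while narrating increases
as positive, so renderers print magnitudes with direction words. When a
patient has several scans inside one phase, the earliest is used.

Signed-rank: zeros dropped (Wilcoxon's original), exact null distribution
for n ≤ 25 without tied magnitudes, otherwise normal approximation with
continuity and tie correction. Rank-sum: exact for min(n) ≤ 10 without
ties, else tie-corrected approximation. Fisher: two-sided hypergeometric
summation over tables at most as probable. All three are delegated to
scipy behind this package's interfaces; the test suite proves exact-mode
equality with brute-force enumeration over the full small-sample space
(every sign pattern to n = 8; every group arrangement to n = 8; every 2×2
table with margins ≤ 12).

Summaries report mean ± SD per measure × phase × stratum (SD undefined at
n = 1 is reported missing with a warning) and mean volume ratios in % of
TIV. Post-shunt phases are compared to baseline by signed-rank on
patients observed in both. Between strata, baseline values are compared
directly but post-shunt phases are compared on relative changes — the
response, not the patient's absolute anatomy — otherwise a genuine
baseline stratum shift (e.g. the Alzheimer contrast) would masquerade as
a treatment-response difference. No multiplicity correction is applied by
default, mirroring the single-comparison convention of the source
analysis; `holm=True` enables Holm adjustment.

Simulator calibration (verified in the acceptance tests): with all
effects at 1 the early-phase signed-rank rejection rate over 1000
replicate cohorts is 0.05 (band 0.03–0.07); with default effects at
n = 500 every phase multiplier is recovered within 5% (the
outcome-attenuation mixture and lognormal mean shift account for ~1–3% of
that) and the early ventricular decrease is detected in ≥ 95% of 200
replicates.

## Problem sizes

Phantoms are voxelized at 1 mm (≈ 3.3M voxels; a 0.5 mm consistency check
uses ≈ 26M), ten randomized phantoms per recovery run; calibration uses
1000 null replicates at n = 54 and 200 effect replicates at n = 500.
These sizes make the full test suite and the acceptance script each run
in well under a minute of compute on a single CPU.

## Known limitations

* Labeled compartments are inputs; the package deliberately contains no
  anatomical segmentation of real MRI.
* The phantom's analytic indices assume the AC–PC line is parallel to the
  y axis (the generator enforces this); measurements themselves accept
  oblique landmark pairs.
* Voxel measurements carry the quantization bounds described above; at
  1 mm the BVR is systematically low by ~1–3% on steep-roofed geometry.
* The cohort simulator is measurement-level: it encodes group-mean
  dynamics and noise, not biophysics, and clinical scores are out of
  scope.
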