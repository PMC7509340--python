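# Methods

`nirsroi` implements region-of-interest (ROI) hypothesis testing for fNIRS
in channel space: instead of reconstructing images from scalp measurements,
an anatomically defined brain region is projected *forward* into a vector of
channel weights, and that weighted combination of first-level GLM
coefficients is tested against zero. This note records the models, the
parameters that matter, and the choices made where the design was open.

## The statistical model

Per channel, measured intensities are converted to optical-density changes
`dOD(t) = -ln(I(t)/I0)` (baseline `I0` = scan mean by default) and, for
two-wavelength data, to oxy-/deoxyhemoglobin changes by inverting the
modified Beer–Lambert law `OD_l = l·DPF_l·(eps_HbO dHbO + eps_HbR dHbR)`.
Each channel's series is regressed on a design of event boxcars convolved
with the canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6,
peak-normalised) plus an intercept:

    Y = X beta + eps.

Channels are modelled as independent, so `cov(beta)` is block-diagonal
across channels. Noise is AR(p) with p = 5 by default: an OLS pass
estimates residual AR coefficients by Yule–Walker (MLE variant), the data
and design are prewhitened by the fitted AR filter (dropping the first p
rows), and the GLM is refit; `iid` is available as a fallback. Any linear
hypothesis over (channel, condition) coefficients is tested with

    t = (c . beta) / sqrt(c' cov_beta c),

two-sided, at the prewhitened residual degrees of freedom. An all-zero
contrast is degenerate by construction and is reported as `t = 0, p = 1`
rather than an error — this is the behaviour that matters for the two-ROI
uniform test below. Group results combine subjects by inverse-variance
fixed effects (`se = (sum 1/se_i^2)^(-1/2)`, pooled dof); a simple
DerSimonian–Laird random-effects alternative is a switch.

Plug-in prewhitening is known to be anticonservative for short series; with
the default 10-minute scans at 4 Hz the single-subject null false-positive
rate at alpha = 0.05 is within Monte-Carlo error of 0.05, which is why the
default scan length is not shorter.

## Contrast vectors

* **Tapered** (the method under study): `c_ROI = normalize(L · mask)`,
  where `L` is the channel x cortex-node sensitivity matrix and `mask` the
  0/1 ROI indicator. Weights are nonnegative and sum to one; they peak on
  the channel most sensitive to the region and taper with relative
  sensitivity. Normalisation makes the weights invariant to any global
  rescaling of `L`, so the extinction coefficient at the (single) forward
  wavelength is irrelevant. A region whose projection is numerically zero
  on every channel (a blind spot) raises an explicit error; the analysis
  drivers record such cases as "no evidence" (`p = 1`).
* **Uniform** (the conventional comparator): weight `1/n` on the `n`
  channels whose source–detector midpoints are nearest the ROI centroid in
  3-D; `n = 4` for the sparse probe and a quarter of the channels (115/460)
  for the dense probe. Ties break by channel index.
* **Difference**: elementwise subtraction of two normalised contrasts (sums
  to zero; not re-normalised). Two nearby ROIs can select identical
  nearest-channel sets, making the uniform difference exactly zero — the
  tapered difference never vanishes for non-identical regions.
* **Conditions**: multi-condition tests use the Kronecker product
  `c = c_ROI ⊗ c_COND`, channel-major.

## Synthetic head

Coordinates are right-handed, in mm, origin at the head centre: +x toward
the right ear, +y toward the nasion, +z toward the vertex; the midsagittal
plane is x = 0. The scalp is a triaxial ellipsoid with fixed axis ratios
(y:x = 1.25, z:x = 1.15); its absolute scale is set so the horizontal
contour at Fpz's elevation — the ring along which head circumference is
conventionally measured (about 10% above the nasion–inion contour) — has
the requested circumference. 10-20 landmarks are placed by the standard
proportional fractions (Fpz/Oz at 10% of the front-over-vertex-to-back arc,
T7/T8 at 10% of the ear-to-ear arc, Cz at the vertex). Scalp and cortex
nodes are sampled on elevation rings with even per-ring counts and
azimuths symmetric about zero, which makes the node sets *exactly*
mirror-symmetric in x; mirroring an ROI is therefore an index permutation
that preserves cardinality.

Cortex nodes sit below the scalp along the local normal at a configurable
depth. The default depth profile varies smoothly between 13 and 35 mm
(`24 + 11·cos(2.2·azimuth)·cos(1.5·elevation)`), emulating the
gyrus-to-sulcus range of real cortex, plus a posterior patch at 48 mm —
beyond the 40-mm reachability cutoff, so unreachable-cortex code paths are
exercised by default. Depth is the dominant visibility factor (channel
sensitivity decays roughly exponentially with depth), and this variation is
what makes ROI detection nontrivial; a constant-depth shell is available
(and used in tests) where analytic depth matters. Proportional resizing
multiplies every coordinate by the circumference ratio, so node indices —
and hence index-defined ROIs — transfer across head sizes with their
relative extent preserved.

## Probe layouts and registration

The **low-density probe** is an alternating source–detector chain: 9
sources and 8 detectors at 25-mm pitch (16 adjacent-pair channels), with
the middle source at the layout origin, anchored to Fpz, and attractors at
(±200, 0) → T7/T8 and (0, 100) → Cz. The **high-density probe** places 36
detectors on a 9x4 square lattice of pitch 13·sqrt(2) ≈ 18.385 mm and 30
sources at half-cell offsets; all source–detector pairs in the four nominal
separation classes (13, 30, 40, 48 mm) are measured — exactly 460 channels.

Registration maps the flat layout onto the scalp in three steps:

1. **Wrap**: layout x walks the azimuthal ring through the anchor by true
   arc length; layout y then climbs the meridian, with each point's azimuth
   resolved on its own elevation ring. This preserves geodesic distances
   along the layout axes.
2. **Orientation**: each attractor defines a probe axis direction; a
   displaced attractor binding rotates that axis. Attractors along the
   layout y axis rotate the whole layout (centreline), left/right
   attractors additionally rotate their arm — for the default error model
   (10-mm displacement SD) the implied 95% rotation bounds are
   arctan(19.60/100) ≈ 11.09° (centreline) and arctan(19.60/200) ≈ 5.60°
   (arms). The displaced anchor binding point is pinned to its landmark (a
   hard constraint), so the probe origin ends up displaced along the scalp
   by the anchor error.
3. **Relaxation**: a damped Gauss–Newton least squares over all points:
   pairwise 3-D distances between nearby layout points (within 60 mm, plus
   4 nearest neighbours) are pulled toward their 2-D layout values (weight
   1.0), weak springs (weight 0.1) toward the oriented wrap positions pin
   the rotational freedom, and every step is solved in the points' scalp
   tangent planes and projected back onto the surface. Convergence is a
   relative cost change below 1e-6 (or a sub-0.1-µm step), max 200
   iterations. A flat probe cannot embed isometrically on a curved scalp;
   the compromise keeps 25-mm channels within ~7% and dense-probe channels
   within ~3 mm of nominal.

Subject-level placement uncertainty follows the simple error model:
circumference ~ N(420, 50²) mm (redrawn below a 250-mm floor) and
independent N(0, 10²) mm displacements of the anchor and attractor binding
points along the layout axes.

## Forward model

Channel sensitivities come from closed-form diffusion theory for a
homogeneous semi-infinite medium with an extrapolated boundary. With
absorption `mua`, reduced scattering `musp`, `D = 1/(3(mua+musp))`,
`mueff = sqrt(mua/D)`, source depth `z0 = 1/musp` and extrapolated-boundary
distance `zb = 2·A(n)·D` (Groenhuis A, refractive ratio n = 1.45), the
two-point function is the buried-source/image-source pair evaluated in the
optode's local frame, where "depth" is measured along the scalp normal at
that optode — this is how the two slab solutions become obliquely oriented
on a curved head. The three-point (channel) sensitivity is the Rytov form

    S(s, d, r) = G(s, r)·G(r, d) / G(s, d),

symmetric in source and detector. Defaults are a single wavelength at
808 nm with `mua = 0.0191 /mm`, `musp = 0.66 /mm` (typical adult-head
values); all are configurable. Entries for cortex deeper than 40 mm are
computed, not zeroed — the 40-mm figure is a reporting/classification
cutoff only.

## Simulation study

Each group draws `n_subjects = 5` subjects. Per subject: sample a
circumference and binding displacements, rescale the head, register the
probe *with* those errors, and compute the true sensitivity matrix; project
`amplitude x mask` through it; multiply by the task time course (canonical
HRF convolved with 2-s boxcars at exponentially distributed inter-stimulus
intervals, mean 30 s, over a 600-s scan at 4 Hz); add independent AR(5)
noise per channel (template coefficients 0.72, 0.12, 0.06, 0.04, 0.02 —
strongly serially correlated, as fNIRS physiology is).

**SNR definition.** The noise SD is calibrated once per dataset: it equals
the evoked-signal SD that a *well-covered reference region* of the same
radius (the covered cortex node nearest an optode, under the standard
420-mm registration) would produce at its best channel, divided by the
configured SNR. Poorly visible regions — deep cortex, blind spots,
misplaced probes — therefore genuinely suffer a lower effective SNR. The
alternative (rescaling the noise to each realised region) would cancel
exactly the visibility variation the method is designed to handle and make
every covered region equally detectable. When a subject is simulated
standalone without a reference, its own maximum-channel evoked SD is used,
so the realised evoked-to-noise ratio at that channel equals the configured
SNR exactly.

ROI centres are drawn uniformly at random over left-hemisphere cortex
nodes whose *scalp projection* lies within the ROI radius of an optode
(lateral coverage; depth does not disqualify a centre). The mirrored
right-hemisphere region is the noise-only null. In two-ROI mode a second
centre is drawn at the configured centre-to-centre separation (tolerance:
one node spacing) and activity is generated in the first region only; the
mirrored pair supplies the null difference.

Analyses run in four conditions per group: tapered/uniform weighting, each
with the registration **known** (contrasts from the subject's true
error-bearing registration on the subject's head) or **unknown** (contrasts
from the unperturbed 420-mm standard registration). Simulated chromophores
default to HbO (scale 1) and HbR (scale −0.4, sharing the HbO-calibrated
noise level, hence a proportionally lower effective SNR).

What the generator deliberately does **not** emulate: physiological
rhythms (cardiac/respiratory/Mayer waves), motion artifacts, per-subject
amplitude variability, real gyral/sulcal anatomy or parcellations,
heterogeneous tissue layers, and two-wavelength coupled measurement noise.
Passing tests therefore demonstrate the statistical machinery and the
geometry/visibility mechanism, not performance on any specific real
dataset.

## Evaluation

Significance scores are `1 − p`; the AUC is the Mann–Whitney probability
(ties counted half) that an active region is more significant than a null
region, identical to the trapezoid of the stored threshold-sweep curve.
Two methods scored on the same simulated instances are compared with the
paired DeLong estimator of the variance of the AUC difference (placement
values per instance; covariance across methods), `z = |dAUC| / se`,
two-sided normal p; an unpaired fallback exists. Type-I calibration plots
the empirical fraction of null p-values below each nominal level on a grid
of 512 levels plus 0.05 exactly.

At the headline design (radius 14 mm, SNR 1, 5 subjects, low-density
probe), 500–800 group replicates give AUCs of roughly 0.95 (tapered,
known), 0.93 (tapered, unknown), 0.92–0.93 (uniform), with the tapered
advantage largest when the registration is known and the tapered null
false-positive rate at alpha = 0.05 inside the binomial band. Those
replicate counts are also the problem sizes used by the acceptance checks.

## Numerical and degenerate-input choices

* Registration is deterministic given (layout, head, error); per-pair
  weights and convergence tolerances as above.
* `select_second_roi` candidate tolerance: one node spacing (configurable).
* Nearest-channel ties in the uniform contrast break by channel index
  (stable argsort).
* Blind-spot regions raise `BlindSpotError` at contrast construction; group
  drivers convert them to "no evidence" (excluded subject; `p = 1` if no
  subject contributes).
* All-zero contrasts (uniform differences of coincident channel sets) give
  `t = 0, p = 1` exactly.
* The circumference sampler redraws below 250 mm to exclude degenerate
  heads.
* Events that cannot finish within the scan are not started (an event in
  the final sample would contribute an all-zero regressor).

## Limitations

The ovoid head is an idealisation: real heads are neither mirror-symmetric
nor ellipsoidal, skull/CSF layering shifts effective optical properties,
and the smooth depth undulation only caricatures sulcal geometry. The
slab-based forward model is an approximation to transport-level solvers;
interfaces to finite-element or Monte-Carlo models are out of scope. The
three-measurement (circumference + nasion–inion + ear-to-ear) ovoid resize
is reduced here to the single-measurement proportional case. Group
inference is fixed-effects by default, appropriate for the simulation's
homogeneous amplitudes but not necessarily for real cohorts.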