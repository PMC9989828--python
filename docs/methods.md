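# Methods

## Transfer-event model

A lipid-transfer event is defined operationally on tracking output: two
droplet tracks are in contact, the smaller one shrinks, and at the
completion time `tmax` its track merges into the survivor. The droplet
whose volume vanishes at `tmax` is the donor. Volumes follow

    Vd(t) = Vd0 * (1 - exp(Rd * (t - tmax)))
    Va(t) = Va0 + (Vamax - Va0) * exp(Ra * (t - tmax))

for `t <= tmax`, i.e. exponential approach to completion: transfer starts
slowly and accelerates, with the rate constants `Rd`, `Ra` (1/s) measuring
that acceleration. `Vd(tmax) = 0` and `Va(tmax) = Vamax` identically. The
model is written backward from `tmax` on purpose — `tmax` is the one time
point the data pin down sharply (the track merge), so it is held fixed
during fitting and only the five parameters `(Vd0, Rd, Va0, Vamax, Ra)`
are free, fitted independently for donor and acceptor by bounded nonlinear
least squares (`scipy.optimize.least_squares`, trust-region reflective,
analytic Jacobians).

Assumptions: droplets are spheres of uniform dye density; transfer is a
single pairwise process (no third partner); volume is conserved across the
pair, though conservation is deliberately *not* imposed on the fits —
`Vamax` is free, so conservation can be checked a posteriori rather than
assumed.

### Fitting details

* Initialization: `Vd0` from the first observed volume; `Rd` from a
  log-linear regression of `log(1 - V/Vd0_init)` on `t - tmax` (the model
  is linear in that space). Acceptor analogous, with `Vamax` initialized
  from the tail of the trace.
* Bounds: rates in `[1e-6, 1]` 1/s; volumes positive. Physiological rates
  are 1e-3 to 1e-1 1/s, far from both bounds.
* At least 4 samples strictly before `tmax` are required; samples at or
  after `tmax` are dropped (the donor no longer exists there).
* Degenerate traces are flagged rather than fitted silently: a rate pinned
  at a bound, a flat acceptor (`Vamax - Va0 ~ 0`), or a donor trace with
  < 2% head-to-tail decline (such a trace is consistent with *any*
  sufficiently fast transfer completing between the last two frames, so
  `Rd` is unidentified) all set `converged = False` with a message.
* Standard errors come from the Gauss–Newton covariance
  `(J'J)^-1 * SSE / (n - p)` at the solution.

### Multi-transfer filter

Within a single pairwise event the donor's and acceptor's rate constants
must agree, so `|log10(Ra)/log10(Rd) - 1| >= 0.4` marks events likely
involved in additional simultaneous transfers; they are excluded from rate
cohorts, as are donors in contact with more than one acceptor. The ratio
is ill-posed when `|log10(Rd)| <= 0.05` (i.e. `Rd` within ~12% of 1/s);
such events are excluded with an explicit reason. This never triggers at
physiological rates and only guards against division blow-up.

### Event window

The fitted window opens at the first in-contact frame where the donor
volume has dropped below 98% of its pre-contact median — "in contact" alone
is not "transferring", and early in-contact frames with a still-constant
donor would otherwise dilute the fit. The window closes one frame before
the merge.

### Manual-style quantities

The average transfer rate is the endpoint difference `(V_start - V_end) /
(t_end - t_start)` over the event window, reported in µm³/h; sphere volume
from measured diameters is `(pi/6) * mean(d)^3`. Cohorts are summarized by
median and IQR (Q3 − Q1, linear-interpolation quantiles; the rate
distributions are long-tailed, so means are avoided).

## Detection and tracking

Segmentation (per 3D frame): physically isotropic Gaussian smoothing
(sigma = 1 xy voxel, z scaled by anisotropy), Otsu threshold (fixed
override available), hole filling, 26-connectivity labelling, and a
distance-transform watershed that splits touching droplets (seeds from
anisotropy-aware EDT maxima separated by >= 0.25 µm). The watershed is on
by default: during transfer the donor stays tangent to its acceptor, and
without splitting the pair would collapse into one component at first
touch, moving the apparent `tmax` onto `t_contact`. With splitting, the
merge happens when the donor falls below the seed resolution — at these
rates within seconds of the true completion, i.e. within one frame.
A blank-frame guard requires the brightest smoothed voxel to stand
6 robust SDs above the median before Otsu is attempted, since Otsu on pure
noise would split the noise floor itself. Detections below 0.05 µm³ are
discarded. Volumes are voxel counts times the anisotropic voxel volume
(e.g. 0.12 × 0.12 × 0.4 µm³).

Linking is greedy nearest-centroid in µm with a 1 µm/frame displacement
gate (droplet motion between frames is small compared with droplet
spacing); candidate links are consumed in order of increasing distance
with volume-difference tie-breaks, making the result independent of
detection order. A track unmatched beyond the gap tolerance dies; a track
whose neighbourhood detection was claimed by another track is terminated
with a merge record (`merged_into`, `merge_frame`), the larger-volume
track continuing. The merge gate adds the claimed detection's equivalent
radius to the displacement gate, because the donor's last centroid lies an
acceptor-radius away from the merged blob's centroid.

Contacts: two droplets are in contact in a frame when their masks, each
dilated by one voxel, share a voxel. This reads the "detected within the
same pixel" criterion in 3D voxel terms; a strict shared-voxel mode
(`dilation_voxels=0`) is available. Contact onset resolution is about one
frame provided the approach speed is at least a voxel-plus-dilation per
frame; slowly drifting pairs are flagged earlier than their true touch
time by up to the dilation margin.

## Interface geometry

Monolayer traces (ordered control points per tomographic z slice, z steps
of 0.71–0.75 nm in real tomograms) are interpolated per slice with an
arc-length-parameterized natural cubic spline — exact at the control
points — then blended linearly in z onto a grid regular in both z and
normalized arc position at 2-nm spacing. Open curves per slice match the
topology of manual traces; self-intersecting slice polylines are rejected.

Distances are nearest-neighbour Euclidean point-to-point between the two
2-nm grids (A→B), which converges to the true surface distance at this
resolution; grid points of A farther than 50 nm from B (configurable) are
outside the apposed region and excluded from statistics. Min, max, mean,
median and SD are reported per interface; the median is the per-interface
summary because the distributions are skewed. A→B and B→A medians agree
within twice the grid spacing on smooth surfaces; the package computes
A→B.

Sphere radii from two parallel cross-sections of radii `a`, `b` spaced
`z`: `r = sqrt(a^2 + ((a^2 - b^2 - z^2)/(2z))^2)`. The inner term recovers
the height of the first section above the equator, making the formula an
exact inverse of sphere sectioning (verified to machine precision over
randomized cases); an equatorial section gives `r = a` directly. Circle
radii from traced arcs use an algebraic (Kåsa) least-squares circle fit.
Diameter ratios are reported large/small, >= 1 by construction.

## Synthetic data

The generator emulates confocal live imaging of LipidTOX-stained LDs:
0.12 µm pixels, 0.4 µm z sections, 20-s frames (the acquisition geometry
of the live data this pipeline targets). Droplets are solid spheres of
unit fluorophore density rasterized by 3× supersampled sphere–voxel
overlap (~1% volume accuracy); the PSF is a Gaussian with physically
isotropic sigma (default 0.15 µm); intensities are
`Poisson(photon_scale * signal + background) + N(0, read_noise_sd)` from a
single seeded generator per movie — identical configs are bit-identical.
The dye's photon statistics are instrument-dependent, so `photon_scale = 200`,
`background = 10`, `read_noise_sd = 2` were chosen once as
confocal-realistic values giving peak SNR ≈ 40 and segmentation volume
errors of ~5–10%, comparable to what threshold segmentation of real
confocal data achieves on µm-scale droplets. During transfer the donor is
kept tangent to its acceptor (centers move as radii change) so the contact
criterion stays exercised; before contact the donor drifts linearly onto
the tangent point. Event truth tables enforce `Vamax = Va0 + Vd0` exactly.

Trace-level cohorts (`simulate_event_traces`) skip imaging and attach 5%
multiplicative Gaussian noise to model volumes — the volumetric error
level of the imaging pipeline at the defaults — with `Rd` log-uniform over
0.002–0.022 1/s, the physiological range of donor rate constants, and
observation windows of ~4/Rd (8–80 frames) so the informative part of the
exponential is sampled.

What the generator does **not** emulate: realistic PSF side lobes and
depth dependence, droplet motility and crowding, photobleaching,
background structure, out-of-focus light, or cryo-ET image formation
(surfaces are abstract point sets). Passing tests therefore demonstrate
correctness of the measurement and fitting machinery under controlled
conditions, not robustness to every pathology of real microscopy.

## Problem sizes and numerical choices

The validation suite uses desk-scale problems: 35–40-frame movies of
15 × 80 × 80 to 16 × 160 × 160 voxels with 1–5 events, 100-event
trace-level cohorts, 200 × 200 grid searches, 1000 random sphere
sectionings, and ~100 × 100 surface grids. The grid-search oracle
comparison counts agreement at one-grid-cell tolerance per parameter;
because the SSE valley is diagonal in `(Vd0, Rd)`, the optimizer
occasionally finds a strictly lower SSE than every grid node while the
discrete argmin sits just over one cell away, so cohort agreement
slightly below 100% still indicates a correct optimizer. Optimizer
tolerances are set to 1e-14 (xtol/ftol/gtol) so noiseless recovery reaches
1e-6 relative error with margin. Quantiles use linear interpolation
throughout.

## Known limitations

* The segmentation/tracking recipe is validated against synthetic ground
  truth, not against any external reference implementation; on real data
  segmentation choices (threshold, watershed seeds) will dominate volume
  accuracy.
* Greedy linking is adequate for sparse, slow droplets; dense fields would
  need global assignment.
* Donor volumes are biased slightly high by thresholding of blurred
  spheres; rate constants are insensitive to this, absolute volumes less
  so.
* Nearest-neighbour surface distance underestimates separation where one
  grid ends (edge effect); the median over the interface region is robust
  to this, the max is not.
* Events shorter than 5 frames before `tmax` cannot be fitted (4-sample
  minimum).
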