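# Methods

`nucleomech` quantifies four imaging/gel readouts used to ask whether
actin–MKL1 activity mechanically compresses the nucleus and closes
chromatin: nuclear-envelope tension by sensitized-emission FRET, chromatin
mobility by FRAP, nuclear geometry by 3D volumetry and 2D circularity, and
chromatin accessibility by DNase I gel densitometry. Raw data for these
assays are rarely deposited, so the package ships a synthetic ground-truth
generator and validates every stage by parameter recovery.

## Correction cascade (core_io)

All image quantification runs through the same cascade, in this order:
background subtraction, illumination-gradient correction, inter-channel
registration, and one pass of 3×3 uniform smoothing ("three-point"
smoothing; the minimal 2D reading of a three-sample box filter,
implemented by direct convolution so invalid NaN pixels contaminate only
their own neighbourhood).

**Background.** The default estimator is the mean of a user-supplied
cell-free rectangle; a constant and a rolling-ball variant (for gels) are
available. Output is clipped at zero and the resolved value is written to
the JSON-lines provenance log.

**Illumination.** No flat-field reference is assumed; a quadratic surface
in (x, y) is fitted to the image itself and divided out, renormalized to
preserve the global mean. Two numerical choices matter:

* the fit is weighted by intensity squared. Illumination is only
  observable where there is signal; an unweighted fit on a sparse scene is
  steered by the clipped-noise background, and because that background
  floor does not scale with channel brightness it breaks the
  proportionality between co-excited channels (in testing this moved a
  bleed-through slope from 0.25 to 0.11). With weights proportional to the
  squared channel, proportional channels get proportional fits and their
  ratio is untouched;
* the fitted gain is clamped to [0.25, 4]: a quadratic extrapolated into
  an empty corner must not amplify noise unboundedly.

In the FRET cascade the donor and FRET channels are acquired under the
same excitation filter and therefore share one illumination field; the
surface is fitted once on their sum and divided out of both, which
preserves their pixel ratio exactly. The acceptor channel (separate
excitation) gets its own fit.

**Registration.** The integer lag comes from masked cross-correlation
(exact for non-periodic content); subpixel refinement is an iterated
linearized least-squares (optical-flow) solve of grad(ref)·d = residual on
lightly smoothed copies. Parabolic interpolation of the correlation peak
was tried first and rejected: on smooth cell scenes the peak is broad and
the parabola is accurate only to ~0.25 px, while the gradient solve is
accurate to <0.05 px at SNR 20. The moving image is resampled bilinearly;
pixels entering from outside the field are NaN (invalid), never
extrapolated. A peak correlation below 0.2 means unreliable registration:
the shift is forced to zero with a warning (this is also how empty
calibration channels pass through the cascade safely).

## Morphometry

**2D.** Gaussian pre-smoothing (0.2 µm), Otsu threshold, hole filling,
connected components. Circularity is 4π·area/perimeter² with the
perimeter from the 4-direction Crofton estimator. Crofton-4 is accurate to
about 1% on discs and ellipses — the shapes nuclei actually take — whereas
pixel-edge counting biases disc circularity low by ~27%. Its known
limitation is anisotropic: for an axis-aligned square the four-angle
quadrature gives perimeter π(1+√2)/2·s (≈5% low), so a square measures
≈0.87 rather than the continuum π/4 ≈ 0.785. Values are reported
unclipped, and components under 9 px are refused (the estimate is
meaningless there).

**3D.** The stack is smoothed with a physically isotropic Gaussian
(default 0.2 µm — deliberately sub-nuclear; the 0.002 mm "surface detail"
setting of the original Imaris workflow is a rendering granularity, not a
filter width), thresholded globally by Otsu (a deterministic, parameter-
free stand-in for an unpublished auto-threshold), and hole-filled.
Touching nuclei are split by seeded watershed on the Euclidean distance
transform computed with physical voxel sampling, so the 2.5× z-anisotropy
does not skew the split. Seeds are EDT maxima clustered by a ridge test —
two maxima joined by a path whose EDT stays ≥ 0.9 of the shallower peak
belong to one (elongated) nucleus, because an ellipsoid's medial ridge has
ratio ≈1 while even a strongly overlapping sphere pair has a saddle at
√(1−(d/2r)²) < 0.95 for d > 0.6r — then greedily thinned to a minimum
separation of `seed_point_diameter` (default 6 µm ≈ a small nucleus), with
deterministic tie-breaking (deeper peak first, then lexicographic voxel
order).

Quality flags: objects touching the xy border are `border_touching`
(z-truncation is pervasive in confocal stacks and only warns); components
with more ridge-separated candidates than accepted seeds are
`unresolved_merge`. Flagged objects stay in the label map but are excluded
from population statistics, mirroring the original practice of discarding
nuclei that could not be segmented confidently. Volume is voxel count ×
(0.25 × 0.1 × 0.1) µm³; group comparisons use the two-tailed unpaired
t-test.

At these settings, digitized spheres of r ≥ 2 µm measure within 5% of
closed form (error falling with radius), and 60-nucleus populations drawn
at each of the six printed group distributions recover their mean volume
within ~3%.

## Sensitized-emission FRET

Donor leakage x and acceptor cross-excitation y are the slopes of
pixel-wise FRET-channel intensity against the donor (donor-only sample)
or acceptor (acceptor-only sample) channel, over foreground pixels
(above 3× the image noise SD, estimated from robust lag-3 pixel
differences — histogram-based estimators fail on dense specimens). The
fit is orthogonal (Deming) least squares using the measured noise-variance
ratio of the two channels: both channels carry detector noise, and a
plain y-on-x regression attenuates the slope (errors-in-variables) by
5–10% under realistic SNR — enough to corrupt the index. On noiseless
data the Deming slope equals the ordinary one. A free intercept is
reported as a diagnostic; r² < 0.5 rejects the calibration sample, and a
Theil–Sen fallback is available for outlier-heavy samples.

The index map is (F − x·D − y·A)/A on cascade-corrected, registered,
smoothed channels, defined only where A exceeds 3× its noise SD (the
ratio is unstable at low acceptor); undefined pixels are NaN, never zero.
Per-cell means are taken over the defined pixels of each mask (manual
label masks take precedence; a 0.5–1.5 µm perinuclear ring can be derived
automatically). The quantity is sensitized emission normalized by
acceptor, not FRET efficiency; no efficiency conversion is attempted.

## FRAP double normalization

Per frame, I_t = (ROI1 − ROI3)/(ROI2 − ROI3) removes background and —
because any per-frame multiplicative loss hits ROI1 and ROI2 alike —
acquisition photobleaching cancels exactly in the ratio. The curve is then
I = (I_t − I_4)/(I_ave − I_4) with I_ave the pre-bleach mean (three frames
in the reference protocol) and I_4 the first post-bleach I_t. Pre-bleach
frames are passed through the same transform rather than pinned to 1, so
both anchors (first post-bleach I = 0, pre-bleach mean = 1) are exact by
construction and testable to machine precision. I_ave ≤ I_4 ("no
detectable bleach") and ROI2 ≤ ROI3 are hard errors.

Summary statistics come from a single-exponential fit
I(t′) = m(1 − e^(−t′/τ)) over post-bleach frames, t′ zeroed at the first
post-bleach frame (original timestamps retained; the acquisition schedule
is always read from the data, never assumed). The mobile fraction m and
half-time τ·ln 2 are the simplest parameters consistent with one bleached
compartment; values m > 1 are flagged, > 1.2 rejected.

## Gel densitometry

A lane profile is the per-row mean across the lane rectangle; background
is the mean of two flanking inter-lane strips (5 px each) by default, with
rolling-ball and constant alternatives. Normalization is
I = (I_n − I_b)/ΣI_n − I_b) with negatives clipped before summation (the
clipped mass is reported), so every non-empty lane sums to exactly 1 and
the profile is invariant to exposure gain. Ladder bands are local maxima
with ≥5% prominence; migration→size is piecewise-linear in log10(size),
defined only within the ladder span (no extrapolation — out-of-span mass
is reported, and >20% warns). Re-binning onto a log-size grid moves
discrete masses, so total mass is conserved exactly and the per-bin
density (mass per Δlog10 size) absorbs the Jacobian of the nonlinear
mobility map. The accessibility score of a lane is its mass fraction below
500 bp: at a matched DNase dose, smaller fragments mean more accessible
chromatin.

## Synthetic ground truth

Every generator is a pure function of (parameters, seed).

* **Nuclei stacks** — randomly oriented ellipsoids; volumes lognormal,
  moment-matched to a stated (mean, SD) — positivity with only two printed
  moments; mild aspect ratios (1–1.4). Default imaging: 256×256×80 voxels
  at 0.25/0.1/0.1 µm, Gaussian PSF σ = 0.2 µm laterally and 0.4 µm
  axially, Poisson-Gaussian noise at SNR 20. Populations larger than one
  field can hold are spread across several fields, as in a real confocal
  session. Group means/SDs default to the published values (e.g. 207 ± 58
  µm³), so recovery tests are table-driven.
* **FRET scenes** — donor and acceptor co-localized in perinuclear rings
  (tension-sensor geometry) with a deliberately narrow (±3%) expression
  spread: the scenes isolate the effects under test (leakage x,
  cross-excitation y, per-excitation illumination gradients, inter-channel
  pixel shift, noise), not transfection heterogeneity. Calibration samples
  are dense fields of blob-like cells spanning a wide intensity range —
  what conditions a slope fit well. Noise is Gaussian at (channel
  maximum)/SNR per channel, emulating shot-noise scaling: a dim channel is
  also a quiet one.
* **FRAP traces** — single-exponential recovery with bleach depth, mobile
  fraction, τ, optional per-frame acquisition decay applied equally to
  bleached and reference ROIs, Gaussian noise as a fraction of the
  pre-bleach amplitude; schedule = 3 pre-bleach frames, ~20 s bleach gap,
  10 frames at 0.78 s, 30 at 2 s.
* **Gels** — Gaussian bands placed by a fixed log-linear mobility law
  anchored at the ladder extremes, plus a ladder lane, offset and noise.

What passing these tests shows — and does not. Recovery on ellipsoids with
a Gaussian PSF bounds algorithmic error (thresholding, splitting,
anisotropy handling), not optical error: real nuclei are irregular, real
PSFs have diffraction structure, real gels have smile and lane distortion,
and real FRAP recoveries are not single exponentials. Absolute accuracy on
real data therefore depends on acquisition quality in ways these synthetic
scenes cannot probe.

## Problem sizes

The validation suite runs each printed volume group at its published n
(60 nuclei) and field geometry; FRET scenes use 16 cells on 320² px;
Monte-Carlo suites use 50 seeds (FRAP, gel) and 200 replicates
(group-contrast power). These sizes keep the full suite in the tens of
minutes on a single core while leaving sampling error well inside every
stated tolerance.

## Known limitations

* The Otsu threshold emulates, but cannot reproduce exactly, the original
  interactive Imaris thresholding; absolute volumes on real stacks may
  shift by a few percent (the printed-group recoveries bound this for
  ellipsoidal geometry only).
* Circularity inherits Crofton-4's ~5% perimeter anisotropy for shapes
  with long axis-aligned straight edges.
* The merge flag is heuristic: overlaps with saddle ratio above 0.9 of
  the peak depth are indistinguishable from one elongated nucleus.
* Bleed-through calibration assumes a linear detector and no pH/maturation
  differences between calibration and sensor constructs.
* The gel mobility model is an empirical log-linear interpolation; no
  physical migration modeling, lane finding, or distortion correction.
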