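# Methods

## Measurement model

A passively exposed white filter surface collects light-absorbing carbon by
diffusion and darkens with cumulative exposure. The quantity measured is the
mean pixel intensity (PI) of a square region of interest (ROI) at the center
of the surface in monochrome 12-bit lightbox photographs: integers 0 (black)
to 4095 (white). All ROI pixels of all frames in a session are pooled into a
single arithmetic mean — for a fixed ROI this is identical to averaging
per-frame means, so the choice is one of implementation simplicity, not of
substance. The mean is never rounded; rounding is a reporting concern.

The change in reflectance of sampler S after exposure time T is

    ΔPI[T−0] = (PI_S,T − PI_R,T) − (PI_S,0 − PI_R,0)

with R the unexposed reference surface photographed in the same session.

Properties relied on throughout (and asserted in the test suite):

* **Additive drift cancels exactly.** A session-wide brightness offset b adds
  to both PI_S,t and PI_R,t and drops out of the difference. After 12-bit
  quantization the cancellation holds to within 0.5 PI per pooled mean, and in
  practice far better, since rounding errors average over the ~48 000 ROI
  pixels of a 20-frame session.
* **Multiplicative gain does not cancel.** If the follow-up session has gain
  g, the measured ΔPI is biased by (g−1)·(PI_S,T − PI_R,T) — exactly, at zero
  noise. No correction is applied: the field protocol gives no handle on
  session gain, so the residual is documented instead and bounds the noise
  model below.
* Antisymmetry under swapping sessions; ΔPI ≡ 0 for the reference against
  itself; linearity of the PI ↔ percent-of-full-scale conversion
  (ΔPI / 4095 × 100).

Sign convention: darkening is negative. Reflectance *increases* between
time-points (a known signature of measurement uncertainty at low exposure) are
retained as-is, never truncated.

## Imaging input contract

12-bit data are routinely stored in 16-bit TIFF containers; the reader
accepts such files but treats any pixel above 4095 (for declared 12-bit data)
as a bit-depth error — silent rescaling would corrupt ΔPI. Color images are
rejected. ROIs are addressed explicitly (center pixel + odd side length,
default 49 px, 0-based) via a layout file; automatic surface detection is out
of scope because the lightbox fixes surface positions physically. Any frame
count ≥ 1 is accepted; deviation from the expected count (20 in the standard
protocol) is a QC flag, not an error, as is any frame whose fraction of ROI
pixels at full scale exceeds 1%.

## Series analyses

* **Rates**: secant rates over consecutive sampling intervals and over the
  whole deployment, in PI per day (field) or PI per minute (laboratory
  chamber). The unit travels with the series and is never converted silently.
* **Linear fits**: ordinary least squares of ΔPI on exposure time
  (scipy.stats.linregress); R² is the coefficient of determination.
* **Lower limit of detection**: the earliest sampling time at which every
  sampler observed at that time satisfies |ΔPI| ≥ 1% of full scale (40.95 PI
  at 12 bit). Only samplers deployed since baseline participate; a cohort
  containing a sampler that never crosses reports "not reached". The
  threshold is configurable; LOD time is non-decreasing in it.
* **Saturation (upper limit)**: the replacement-sampler rule. Over a window
  [t0, t1], the original samplers at a location are saturated iff their mean
  change stays within a tolerance (default 41 PI, the measurable-change
  threshold) while a freshly deployed replacement changes measurably and at
  least `ratio_threshold` (default 10) times as much. The ratio denominator
  is floored at 1 PI to stay finite when continuing samplers are flat. The
  field literature reports one worked instance of this probe, not a rule;
  the constants are therefore configurable defaults, and the assessment
  always reports the three underlying quantities alongside the boolean.
* **Period summaries**: per-sampler secant rates within a period, summarized
  by median and IQR using the linear-interpolation quantile convention (the
  most common reporting convention; nothing in the protocol prescribes one).

## Replicate statistics

Pearson r and Spearman s (average ranks for ties) via scipy; CV uses the
sample (n−1) standard deviation over |mean| — replicate counts are 2–3, where
the n−1 convention is standard. RMSE "relative to the replicate mean" pools
deviations of each replicate from its set mean over all sets; for a duplicate
pair this reduces to |a−b|/2 (asserted as a property). RMSE/mean uses the
absolute grand mean, so percentages are positive against negative means.
Agreement tables are computed overall, per sampling date, and per quintile of
pair-mean ΔPI; quintiles rank pooled pair means (least darkening first, ties
broken by stable location order) and split into equal-count groups. Groups
with fewer than 3 pairs are skipped with a warning; zero-variance groups
report correlations as NaN rather than 0 or 1.

The variability decomposition reports unweighted means of group CVs: across
location means per date (among-location), across per-date means per location
(within-location over time), and across replicates per location-date. Whether
to weight by group size is not prescribed anywhere; unweighted is the
simplest defensible choice and is stated here once.

## Synthetic lightbox

The simulator exists so that every pipeline stage has ground truth. A
surface's noise-free trajectory is

    PI(t) = pi_sat + (pi_0 − pi_sat) · exp(−k · D(t)),   D(t) = v_d · C · t

chosen as the *simplest* monotone model with the two observed regimes —
near-linear darkening early (initial rate −k·(pi_0 − pi_sat)·v_d·C) and a
plateau under heavy loading. It is a stand-in, not a physical claim; dose is
only ever the product k·v_d·C in arbitrary consistent units, because no
calibration from reflectance to mass concentration exists.

A rendered session applies, in order: shared multiplicative session gain g,
per-frame multiplicative flicker f_j, shared additive session offset b,
per-pixel Gaussian noise, then quantization (round half away from zero —
platform-stable — and clip to [0, 4095]). Background pixels sit at mid-gray
2048 so a mis-specified ROI is visible in measurements. Identical
configuration and seed give byte-identical TIFFs.

### The default campaign (the stated world)

20 indoor locations × 2 co-located samplers, imaged at days
0/33/55/90/118/173/209/258 — the deployment design of the field protocol this
package supports. Where that protocol states no value, the defaults are fixed
once as follows and not revisited:

* **Baseline PIs**: samplers ~N(3900, 15²), reference 3950 — white paper
  filters imaged below full scale to avoid clipping.
* **pi_sat = 800**: maximal darkening ≈ −3100 PI (−76%), consistent with the
  heaviest field loadings observed (~−71%).
* **Per-location dose rates**: geomspace(3 × 10⁻⁴, 1.3 × 10⁻²) per day. The
  slow end makes the slowest location first cross the 1% threshold between
  days 33 and 55 (the field campaign's observed LOD of ~2 months); the
  ladder puts the median total darkening near −1200 PI (≈ −30%), matching
  the reported median of −27%.
* **Replicate structure**: co-located samplers share the location dose rate
  times a lognormal efficiency factor (sd 5%), emulating small differences in
  placement and collection efficiency.
* **Saturation probe** (opt-in, `replacement_start_time=118`): the fastest
  location runs at dose rate 0.04/day so its original pair is ≈ −3070 PI
  (−75%) and flat (< 41 PI change) over days 118–173, while a replacement
  deployed at day 118 darkens ≈ −2750 PI over the same window — the regime
  in which the replacement rule must fire.
* **Noise**: session offset sd 20 PI (0.5% of full scale), session gain sd
  0.2%, frame flicker sd 0.2%, pixel noise sd 10 PI — the stability scale of
  an enclosed LED lightbox with a machine-vision camera at zero sensor gain.
  The dominant ΔPI error term is the uncorrected gain residual
  (g−1)·(PI_S,T − PI_R,T), worst-case ≈ 6 PI at full darkening.

### What a green test does and does not establish

The simulator reproduces the *statistical structure* the method assumes:
monotone saturating darkening, shared session lighting, frame flicker, pixel
noise, quantization. It does not emulate handling contamination, filter
curvature, insect debris, repositioning error between sessions, or spectral
(color) effects — the real-world terms that make field replicate CVs (~11%)
larger than this simulator's (~3%). Ground-truth recovery therefore validates
the pipeline arithmetic and the design's detectability properties, not the
field accuracy of the method, which remains uncalibrated against gravimetric
or optical standards.

## Numerical choices and degenerate inputs

* Quantization: round half away from zero, then clip — bit-identical across
  platforms (numpy's default rounding is banker's rounding).
* ΔPI is computed from unrounded means; CSVs carry full precision.
* Sessions without a reference surface, samplers without a baseline session,
  mixed full-scale values, duplicate sampling times, zero-variance
  correlation inputs and zero-mean CVs are all hard errors, not imputations.
* The saturation ratio reports |replacement| / max(|continuing|, 1 PI).
* Exposure clock: a replacement sampler's baseline (ΔPI = 0) sits at its
  deployment day on the shared campaign clock; all series invariants are
  stated relative to each sampler's own baseline.

## Known limitations

* No gain-drift correction (documented residual only); a gray-card reference
  or flat-field calibration would be needed to do better.
* The exponential-saturation darkening model is a simulation device; fitted
  early-segment slopes estimate the initial darkening rate with a secant
  bias of order a·t/2 (a = k·v_d·C), which is why parameter-recovery checks
  restrict to a·t ≲ 0.11.
* ΔPI is relative reflectance change, not LAC mass: calibration against
  reference instruments is explicitly outside this package's scope.
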