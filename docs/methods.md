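# Methods

This note documents the models, numerical choices and limitations behind
`epidose`. It complements the README, which states the calibration chain
itself.

## Geometry and conventions

Both detectors are treated as regular lattices at the isocenter plane
(source-to-detector distance 100 cm): the EPID panel with 768 × 1024
pixels at 0.039 cm pitch (30 × 40 cm²) and the ionization-chamber array
(ICA) with 32 × 32 chambers at 0.762 cm pitch (≈ 24 × 24 cm² effective
area, 0.45 cm chamber bore). Physical coordinates are centimetres with
origin on the beam central axis (CAX); `x` is crossline (increasing with
column), `y` is inline (increasing as the row index decreases, i.e. rows
run toward the gantry-target side where support-arm backscatter
originates), and `r = sqrt(x² + y²)`. The CAX defaults to the geometric
panel centre `((n_rows−1)/2, (n_cols−1)/2)` unless metadata overrides
it; no automatic CAX-finding is attempted.

Because the 32-chamber lattice has no chamber exactly on the CAX (the
CAX index is 15.5), "the value at the CAX" is defined as the bilinear
interpolation of the lattice at the CAX index. When the CAX falls on a
lattice node this reduces to that single chamber, so odd-sized grids
behave exactly as a single-chamber normalization.

### Chamber-matched sampling

EPID values are compared with chambers through the mean of the 12 × 12
pixel block (12 × 0.039 cm ≈ 0.47 cm) nearest each chamber position:
block indices `[ceil(u) − 6, ceil(u) + 6)` of the fractional pixel index
`u` per axis. For a position midway between pixels — the generic case
for chamber centres — the block is exactly centred, which keeps the
sampling mirror-symmetric; a nearest-pixel (round-based) placement would
bias mirrored chambers by one pixel, a visible error in the penumbra.
The same block average serves four roles: chamber emulation when the
simulator produces ICA "measurements", matrix construction, output
factors and conversion-fit sampling — one definition, no cross-talk
between conventions.

## Dark/flood-field correction

`G_EPID = (G_raw − DF)/(FF − DF) · FF_mean`, with `FF_mean` the
arithmetic mean of the flood field over the full panel (no ROI
restriction). Pixels with `FF − DF ≤ 0` abort with an error carrying
the offending count; pixels with `0 < FF − DF ≤ 10⁻³ · FF_mean` are
treated as defective and in-filled with the median of nearby valid
pixels (real panels have isolated defects). Negative corrected values
are clipped to zero and counted. Two identities pin the algebra down:
correcting the flood field itself yields the constant `FF_mean`, and
correcting the dark field yields zero. Rescaling the flood exposure
cancels exactly when the dark level is zero; with a nonzero dark level
the offset does not scale with exposure, so the identity is only
approximate — tests therefore exercise it at zero dark level.

## Correction matrices

* **20% rule.** The per-field mask keeps lattice points with dose
  ≥ 20% of that field's maximum — an isodose cut including the field
  interior plus penumbra down to 20%. The merged matrices are therefore
  dense in-field, which is what makes them applicable to arbitrary
  fields.
* **Merge order.** Matrices are merged from the largest contributing
  field to the smallest, each field overwriting the lattice points its
  mask covers; the innermost (smallest) field wins deterministically,
  the result mask is the largest field's mask, and a per-chamber
  `source_side` map records provenance. Restricted to the smallest
  contributor's mask the merged matrix equals that field's matrix
  element-wise — an exact invariant used in the tests.
* **Class selection.** Three merged matrices are kept (9–24, 13–24 and
  18–24 cm contributors) and selected by field size: ≤ 10 cm → small,
  (10, 15] → medium, > 15 cm → large. For modulated fields the size is
  the equivalent square of the region above 50% of the image maximum
  (area A → side √A). The 10 cm boundary is inclusive on the small
  side.
* **Application.** The matrix lives on the chamber lattice and is
  bilinearly interpolated to every pixel; bilinear rather than bicubic
  to avoid overshoot in the penumbra. Outside the mask (and beyond the
  lattice extent) the nearest defined value is held constant — no dose
  is invented outside the calibrated region, and interpolation at the
  lattice nodes reproduces the stored values exactly.

Known boundary behaviour: a field whose 20% region extends past the
mask of the same-regime contributors (e.g. the 10 or 15 cm fields, whose
outer chambers fall in the next regime's territory within the merged
matrix) retains a percent-level asymmetry residual at the field edge.
Fields lying strictly inside their regime's smallest contributor are
corrected to interpolation accuracy.

## Pixel-to-dose conversion

Per tabulated radius (default: the CAX plus 14 chamber radii out to
11.047 cm, sampled along the crossline axis), dose is regressed on the
chamber-matched pixel value by ordinary least squares over the MU
series; repeated acquisitions at the same MU are averaged first. The
default operating mode applies the CAX pair `(a(0), b(0))` everywhere,
since on corrected images `a(r)` is flat; the per-radius table is kept
for diagnostics, interpolated piecewise-linearly in `r` with end values
held.

Standard errors: detector noise is proportional to signal, so the MU
residuals are strongly heteroscedastic and the classical homoscedastic
SE underestimates the slope uncertainty. When every MU level carries
repeats, the repeat-to-repeat relative variance is pooled across levels
and propagated through the OLS weights (a stable, ~2·(levels−1)-dof
estimate); without repeats, HC1 heteroscedasticity-robust errors are
used. The coefficients themselves are plain OLS either way.

Error tables against chamber measurements report
`|D_meas − D_calc|/D_meas × 100`, rounded half-up to one decimal.

Output factors are `OF(s) = [D(s)/D(24)]/[G(s)/G(24)]` from CAX
samples of the square-field suite; this orientation (dose ratio over
pixel ratio) is the one under which `G · OF` is calibrated in the
reference field's pixel-per-dose scale and OF decreases with field size
when the panel over-responds to field-size scatter. Intermediate sides
are linearly interpolated.

## Gamma analysis

Global 2D gamma at the reference (chamber-array) points: the evaluated
distribution — the EPID-derived dose, chamber-downsampled to the same
lattice in the pipeline — is bilinearly supersampled at 10× its native
resolution (configurable) and searched within a radius of 3 × DTA
(configurable); the dose difference is normalized to the reference
maximum and points below the 5% threshold are excluded from the map and
the summaries. A 10⁻⁹ tolerance on `γ ≤ 1` keeps exactly-critical
points (e.g. a uniform 3% offset under 3%/3 mm) passing despite float
rounding. Results are stable to < 0.1 percentage points when the
supersampling factor is doubled (tested). Points whose search window
leaves the evaluated extent use the available region only; an empty
window yields `γ = ∞` (a fail), never fabricated dose. The
implementation is verified point-for-point (< 10⁻⁹) against an
exhaustive scalar-loop search on random grids. Aggregation across
fields reports mean ± sample SD (ddof = 1; a single field reports
SD 0) per criteria set.

## The simulator

`epidose.simulate` emulates the statistical structure the method
assumes, not a transport calculation:

* **Beam** (`BeamModel`): off-axis ratio `1 + 3·10⁻⁴ r²` (≈ 3.6% horns
  at r = 11 cm, typical of a flattened 6 MV beam), erf penumbra with
  σ = 0.3 cm, CAX output `∝ 1 + 0.04 ln(s/10)` (strictly increasing in
  field side s), dose linear in MU at 10 mGy/MU with zero intercept.
* **Panel** (`EpidResponseModel`): gain 715 pixel units/mGy (chosen so
  the fitted conversion slope lands near 1.3·10⁻³ mGy/pixel), dark
  level 50, flood exposure 100 mGy. The flood image carries the beam's
  own horned open-field shape, so dark/flood flattening removes the
  horns from corrected images — the off-axis defect arises by
  construction. Backscatter is an additive term `amp(s) · (y/10 cm) ·
  dose(x, y)` — linear in the inline coordinate, confined to the
  irradiated area, with `amp` piecewise-constant over the three
  field-size regimes (+0.04 for s ≤ 10, 0 for 10 < s ≤ 15, −0.04
  beyond; up to ≈ ±5% edge asymmetry on large fields, the magnitude
  reported for this class of panel). Within-regime constancy is the
  premise that lets one merged matrix correct a whole regime; it is a
  modelling idealization. A field-size response `1 + 0.015 ln(s/10)`
  makes the panel over-respond to field-size scatter, which is what the
  output factor absorbs. Noise is multiplicative Gaussian, default
  0.5% per pixel.
* **Chamber array**: noiseless, sampling the same high-resolution dose
  through the 12 × 12 block average — it is the reference instrument
  and doubles as ground truth for oracle checks.
* **Pseudo-IMRT fields**: sums of 4 weighted rectangular segments with
  random centres/widths; backscatter and field-size response follow the
  composite field's equivalent square.

All randomness flows from one integer seed (default 20210909);
per-acquisition seeds are spawned deterministically, and identical seeds
give identical arrays.

What the simulator does *not* contain — and hence what passing tests do
not demonstrate about clinical data: spatially varying backscatter
kernels (the additive inline-linear term only reproduces the asymmetry
phenomenology), panel ghosting/lag, spectral (energy) effects,
gantry-angle dependence, MLC leaf structure beyond rectangular
segments, chamber-array noise or setup error. The simulated gamma pass
rates are accordingly not comparable to clinically measured ones; they
verify internal consistency of the chain.

## Problem sizes and determinism

Tests and the acceptance script run the chain at the full detector
resolution (768 × 1024 panel, 32 × 32 lattice). The standard session is
22 square fields (3–24 cm, 100 MU), a 10-level MU series (25–600 MU,
three repeats), and 20 pseudo-IMRT validation fields; plumbing tests
use a reduced geometry where only bookkeeping is at stake. With fixed
seeds every reported number is deterministic; pipeline reports contain
no timestamps, so identical configurations produce byte-identical JSON.

## Known limitations

* The three-matrix regime model assumes within-regime similarity of the
  backscatter asymmetry; fields straddling a regime boundary keep
  percent-level edge residuals (visible in the symmetry diagnostics).
* Matrices are stored on the chamber lattice; sub-lattice structure in
  the panel response (finer than 0.762 cm) cannot be corrected.
* The equivalent-square classifier uses the 50% level of the image
  maximum; heavily modulated fields with multiple dose islands may be
  assigned a smaller class than their jaw setting would suggest (a
  per-field override is provided in the pipeline).
* Gamma is 2D, global-normalization only as validated; the
  local-normalization code path exists but is not exercised by the
  acceptance suite.
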