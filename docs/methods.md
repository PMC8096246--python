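# Methods

## Measurement model

The assay tethers two fluorophore-labeled oligos to a gene locus: a
detector (Ch1, red) that marks the locus and serves as an internal
reference, and a sensor (Ch2, green) whose retention depends on the local
density of the probed epigenetic mark. Under the assumptions that (i) both
fluorophores experience the same local background at the locus and (ii)
the rim samples that background without touching neighboring loci, the
rim-corrected ratio

    G/R = (I_Locus_Ch2 − I_Rim_Ch2) / (I_Locus_Ch1 − I_Rim_Ch1)

is proportional to sensor retention per detector molecule. Intensities
enter as **per-pixel means**, not sums, so locus and rim terms are
directly subtractable even though the two masks have different areas; this
makes the ratio exactly invariant to adding a constant to a channel and
exactly linear in per-channel gain (both properties are tested).

Negative corrected sensor signal is clipped to 0 — a locus cannot carry
negative signal. Negative or near-zero corrected *detector* signal instead
invalidates the locus, because the detector signal is what defines locus
existence; "near-zero" means below ε = 3× the standard error of the rim
pixels, so the validity rule adapts to local noise.

Ratios are normalized across specimens by the mean G/R of the
no-exonuclease controls (the condition in which the sensor is never
degraded, i.e. the assay ceiling); the mean of the normalized control set
is therefore exactly 1.

## Pipeline stages and parameter defaults

**Registration.** Chromatic aberration displaces the two emission
wavelengths by a fraction of a micron — a single field-wide 2D
translation at this scale. The shift is estimated on maximum-intensity
projections by FFT cross-correlation of mean-subtracted planes,
constrained to ±`max_shift` (default 10 px; larger shifts indicate
acquisition problems and fail loudly), with a 3-point quadratic fit per
axis for subpixel precision. The detector channel is the reference; the
sensor channel is resampled by the inverse shift (exact roll for integer
shifts, linear interpolation otherwise), border fill is flagged invalid
for rim use. For a pure integer translation the correlation peak is exactly
symmetric, so integer shifts are recovered exactly.

**Segmentation.** Nuclei are segmented from the diffuse nuclear signal of
the reference channel: Gaussian smooth (`smooth_sigma`, default 4 px),
Otsu threshold, hole filling, area filter (`min_area` 500 px). The
threshold is data-driven, so segmentation is invariant to intensity
offsets. A smoothing sigma of 8 px was considered and rejected: combined
with Otsu on high-contrast nuclei it dilates the boundary by several
pixels, biasing areas of small (≈20 px semi-axis) nuclei by ~16%, while
4 px keeps the bias under ~4% and still suppresses noise comfortably at
realistic SNR. Watershed splitting of touching nuclei is available but off
by default — the assay is read on sparse, well-spread fixed cells, and
border-touching nuclei are excluded by default instead.

**Spot detection.** Foci are diffraction-limited, so a single-scale
scale-normalized LoG filter is matched to a user-stated expected spot
diameter (default 5 px → σ = d/(2√2) ≈ 1.77 px). Local maxima are kept
when the response exceeds `min_snr` (default 5) times the robust noise of
the response map, estimated as 1.4826×MAD (the MAD is scaled to a σ
equivalent so `min_snr` has its conventional meaning), and also 5% of the
image's peak response (guards against numerically-zero "peaks" in
noise-free data). A spot's mask is the connected response region above
half its peak. Intensity steps — above all the nucleus boundary — also
excite the LoG; their half-max regions are elongated bands rather than
compact blobs, so candidates whose mask exceeds 4πσ² pixels (≈4× a
matched spot's support) or escapes the 6σ analysis window are rejected.
On simulator defaults this yields ≥95% recall with ≤5% false positives,
and 100%/0% with noise off.

**Pairing and assignment.** Detector and sensor spots are paired greedily
by distance within `match_radius` (default 3 px post-registration), ties
broken by list order — deterministic and symmetric in the two channels.
Unpaired detector spots survive as `detector_only` loci whose sensor
intensity is measured on the detector mask (this is what makes "both
alleles negative" cells quantifiable); unpaired sensor spots are dropped
with a logged count. Each locus belongs to the nucleus under its
detector-spot center; loci on background are dropped and logged.

**Rim and measurement.** The rim is the `rim_width` (default 5 px)
dilation of the locus mask minus the locus, intersected with the nucleus,
minus all other loci dilated by 1 px and any resampling-invalidated
pixels; an empty rim invalidates the locus with a recorded reason. With
z-stacks, the default measures on the max projection; `per_slice` mode
instead computes the ratio on each of the `k_slices` brightest slices
(ranked by detector locus mean) and averages the ratios, which buffers
z-direction chromatic offsets and does not inflate — in practice reduces —
the measurement CV (tested by repeated noise realizations of a fixed
locus).

**Aggregation.** `population` mode keeps every cell with ≥1 valid locus.
`allelic` mode keeps only cells with exactly two valid loci: cells with
more (usually replicated loci in S/G2) or fewer are excluded and counted
in the log. RNA positivity of a locus is taken from an auxiliary
(RNA FISH) channel: the projection is thresholded at median + 5 robust SDs
and a locus is RNA-positive when >50% of its mask overlaps that signal
(`rna_overlap`, configurable).

## Statistical layer

* **Wilcoxon rank-sum** — exact null distribution when the pooled sample
  has ≤12 observations and no ties (small per-cell samples are the norm in
  allelic comparisons, where exactness matters), otherwise the normal
  approximation with tie and continuity corrections. The implementation is
  backed by `scipy.stats.mannwhitneyu`; the test suite checks the exact
  path against a full enumeration of rank assignments.
* **Sample size** — the two-sample normal-approximation formula
  n = ⌈2(z₁₋α/₂ + z_power)² · sd² / δ²⌉ with δ = baseline·(fold−1). A
  t-based iteration was deliberately not used; the normal approximation is
  the convention this assay's power statements follow (1.5-fold, SD 0.5,
  power 0.8, α 0.05 → n = 16).
* **Dynamic-range calibration** — a mixing series in which the labeled
  sensor fraction f is known per condition anchors the assay floor (f=0)
  and ceiling (f=1); any G/R then maps to
  percent-of-max = 100·(G/R − floor)/(ceiling − floor). Per-condition CVs
  estimate technical noise; a least-squares line of condition mean vs.
  fraction (slope, intercept, R²) checks linearity. Condition summaries use
  per-cell mean ratios (pooling loci within a cell first), so cells, not
  loci, are the replication unit.
* **Positivity classification** — a locus is sensor-positive when its
  normalized G/R exceeds a threshold; the default rule is mean + 3 SD of
  the floor-control normalized ratios, kept as an explicit config value
  because no canonical rule exists. Fractions of di+/+, mono+/− and di−/−
  cells sum to 1 by construction.
* Specimens with fewer than 25 analyzed cells trigger a warning, not an
  error.

## Synthetic specimens

The simulator renders what the pipeline consumes: elliptical nuclei
(semi-axes 18–30 px by default) with a smooth chromatin-like multiplicative
texture, a diffuse nuclear level per channel (detector 300, sensor 50
counts — the detector term is what makes nuclei segmentable from their own
background), an additive background (200 counts plus a 0.05 counts/px
gradient), and isotropic Gaussian foci (σ 1.5 px, detector amplitude 2000
counts) whose sensor copy is scaled by the per-focus true ratio and
rendered at chromatically shifted coordinates (default (1.5, −1.0) px), so
the shift involves no interpolation. Noise is Poisson shot noise plus
Gaussian read noise (σ 10 counts), applied last and clipped to the 16-bit
range; a fixed seed makes output bit-identical. Focus z-centers sit on
integer slices away from stack ends so noise-free recovery is exact; foci
keep ≥6·σ_psf mutual separation and a rim-sized margin from the nucleus
boundary, and impossible placements raise an error rather than silently
crowding.

Two condition generators mirror the assay's experimental designs: a
labeled-fraction **mixing series** (true ratio ∝ fraction; one specimen
per fraction) and **heterozygous two-focus nuclei** whose alleles differ
by a stated fold, with a third channel carrying a broader Gaussian blob at
the RNA-positive (low) allele. Parameter-recovery runs use 800×800 px
fields with 25 nuclei (semi-axes 26–36 px) so ≥100 foci fit per condition
in one field.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: hybridization efficiency and probe accessibility
variation, non-Gaussian PSF tails and z-direction chromatic aberration,
nucleolar/heterochromatin intensity structure beyond the smooth texture,
photobleaching, autofluorescence, touching or overlapping nuclei, and
focus brightness heterogeneity within a condition. Recovery accuracy on
synthetic data is therefore an upper bound on real-data performance.

## Numerical choices and degenerate inputs

* Robust noise = 1.4826×MAD throughout (detection threshold, RNA-channel
  threshold).
* Greedy pairing ties broken by (distance, detector index, sensor index).
* Quadratic subpixel offsets clamped to ±0.5 px; peaks at the search-window
  border get no subpixel refinement.
* Flat (zero-variance) registration planes, empty calibration conditions,
  inverted calibration ranges (ceiling ≤ floor), empty control sets, and
  fold ≤ 1 sample-size requests raise errors; an image with no surviving
  nucleus yields an empty label map with a warning.
* A constant image yields I_Locus = I_Rim, an invalid denominator, and a
  flagged (not raised) invalid measurement.

## Known limitations

Single-scale detection assumes foci of similar size; fields mixing very
bright and very faint true foci may lose faint ones to the relative
response floor. Registration is translation-only (no rotation, scaling or
nonrigid correction) and 2D. The probe uniqueness filter is an exact
16-mer multiplicity check against a user-supplied background FASTA — an
intentionally deterministic, desk-scale approximation of a genome-wide
similarity search, not a replacement for it; probe counts on real genomic
targets therefore depend on the background provided. Coordinates are
0-based half-open on the sense strand; tiling uses an exact 20-bp gap so
probe counts are reproducible.
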