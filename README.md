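# evaquant

Quantification pipeline for **two-channel fluorescence ratio assays at gene
loci** — the class of in-situ assays (such as the Epigenetic Visualization
Assay, EVA) in which a *detector* oligo (red, Ch1) marks the position of a
gene locus in each nucleus and a *sensor* oligo (green, Ch2) reports the
local density of an epigenetic mark such as 5-methylcytosine. The assay's
readout is, per locus, the rim-corrected sensor/detector intensity ratio

```
G/R = (I_Locus_Ch2 − I_Rim_Ch2) / (I_Locus_Ch1 − I_Rim_Ch1)
```

where `I_Locus` is the mean intensity over the locus mask and `I_Rim` the
mean over a concentric 5-pixel band around it, inside the same nucleus —
a local background correction that makes the ratio invariant to additive
offsets and exactly linear in per-channel gain.

The package is written for microscopists and epigenetics labs who have
multi-channel TIFF stacks of methacarn-fixed, probe-hybridized nuclei and
want per-cell, per-allele methylation readouts with auditable drop rules.

## What it does

* **Registration** — corrects inter-channel chromatic shift by a single 2D
  translation per field, estimated by normalized cross-correlation with
  subpixel refinement (detector channel is the reference).
* **Nucleus segmentation** — Otsu threshold on the smoothed diffuse signal
  of the reference channel; per-nucleus area/centroid table; border-touching
  nuclei excluded.
* **Locus detection** — single-scale Laplacian-of-Gaussian spot detector in
  both channels; greedy nearest-neighbor pairing across channels. The
  detector channel is authoritative: loci without sensor signal are kept
  (their sensor intensity is measured on the detector-defined mask), which
  is what makes fully unmethylated alleles quantifiable.
* **Ratio quantification** — rim construction (excluding neighboring loci),
  per-channel mean intensities, the G/R formula above, validity flags for
  degenerate denominators; z-stacks measured on the max projection or
  slice-by-slice with ratio averaging.
* **Statistics** — normalization by the mean G/R of no-exonuclease
  controls; dynamic-range calibration from a labeled-fraction mixing series
  (percent-of-max scale, floor/ceiling, technical CV); per-cell allelic
  classification (di+/+, mono+/−, di−/−); per-cell RNA−/RNA+ allelic fold
  ratios; Wilcoxon rank-sum tests (exact for small samples); two-group
  sample-size estimation.
* **Probe design** — tiles 30-mer oligos at exact 20-bp gaps across a
  target sequence, filters low-complexity and non-unique probes, and
  appends the common 3′ detection tail (`TAGTTTCAGCTTTCCGCAAC`).
* **Synthetic specimens** — a ground-truth simulator (elliptical nuclei,
  Gaussian foci with known true ratios, background gradients, chromatic
  shift, shot + read noise, optional z-stacks and an RNA-positivity
  channel) so every stage is testable by parameter recovery without real
  microscopy data.

## Worked example

Simulate a "treated" specimen whose loci carry a true sensor/detector
ratio of 0.6 and a no-exonuclease control at 1.0, then quantify both with
normalization to the control:

```bash
evaquant simulate --out demo      --seed 7 --n-nuclei 8 --foci 2 2 --ratio 0.6
evaquant simulate --out demo_ctrl --seed 8 --n-nuclei 8 --foci 2 2 --ratio 1.0

cat > demo/manifest.yaml <<'YAML'
channels: {detector: 0, sensor: 1}
specimens:
  - {path: specimen.tif, role: test, label: treated}
  - {path: ../demo_ctrl/specimen.tif, role: no_exonuclease_control, label: no-exo}
YAML

evaquant quantify --manifest demo/manifest.yaml --out demo/results
```

`demo/results/summary.json` then contains (abridged):

```json
[
  {"label": "treated", "n_cells": 8, "n_loci": 16,
   "mean_gr": 0.5995, "cv": 0.0236, "shift_dy": 1.404, "shift_dx": -0.936},
  {"label": "no-exo",  "n_cells": 8, "n_loci": 16,
   "mean_gr": 1.0,    "cv": 0.0147, "shift_dy": 1.436, "shift_dx": -0.948}
]
```

Reading: all 16 simulated loci per specimen were detected; the control
normalizes to exactly 1.0 by construction; the treated specimen's
normalized mean G/R of **0.5995** recovers the simulated truth of 0.6
within 0.1%; the estimated chromatic shifts (~1.4, −0.94 px) match the
simulated (1.5, −1.0) px; and the per-specimen CV of ~2% quantifies the
measurement noise at this signal-to-noise ratio. `per_locus.csv` in the
same directory holds one row per locus with all four intensity terms, the
ratio, and validity flags with reasons.

Other subcommands: `evaquant calibrate` (dynamic-range calibration from
`calibration:<fraction>` manifest roles), `evaquant stats` (sample size,
e.g. `--fold 1.5 --sd 0.5` prints `n_per_group: 16`), and
`evaquant design-probes` (FASTA in, tiled/filtered/tailed oligos out as
FASTA + TSV). The same functionality is importable from Python
(`import evaquant as ev`).

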