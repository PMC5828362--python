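# Methods

`pmarray` processes single-channel protein microarray data: slides
printed with antigen spots in pin-deposited blocks, probed with serum
and a fluorescent secondary antibody, quantified by scanner software
into per-spot foreground/background statistics in relative fluorescence
units (RFU). The pipeline turns a folder of per-array quantification
exports plus a GAL layout into a consolidated antigen-by-array matrix
suitable for downstream statistics, which this package deliberately
does not provide.

## Signal model and assumptions

The pipeline assumes a multiplicative bias structure:

```
observed spot intensity ≈ truth × array_gain × block_factor + background + noise
```

* `array_gain` captures scanner PMT settings and assay-run effects that
  scale a whole array;
* `block_factor` captures pin-to-pin deposition differences that scale
  one block (sub-array);
* `background` is the local slide background the scanner estimates per
  spot, together with its standard deviation.

A positive control printed at a **static position in every block at
three concentrations** (low < med < high) is the only lever the
pipeline uses against both bias terms. All methods assume this control
is present in every block; layouts violating that fail validation.

## Pipeline stages

1. **Neighbourhood background correction.** Each spot's local
   background is replaced by the median background over the
   `window × window` patch of grid positions centred on it (default
   3×3), restricted to the spot's own block, truncated at block edges,
   self-inclusive, in a single pass over raw values. Grid
   neighbourhood rather than physical distance keeps the operation
   layout-driven and deterministic; block restriction reflects that
   blocks are printed by different pins with independent background
   behaviour. The median of an even count is the mean of the two
   middle values. A worst-case corner under the default window still
   aggregates 4 values, enough for spike rejection.
2. **Net intensity.** `net = raw_fg − corrected_bg`. Negative nets are
   kept: correction and filtering are separate concerns, and
   sub-background spots are caught by the noise flag.
3. **Noise flag.** A spot is `NOISY` when `net < n · bg_sd` with
   `n = 2` by default (user-tunable). The comparison is **strict**, as
   are all threshold comparisons in the package: a value exactly at a
   threshold is never flagged. With `bg_sd = 0` only negative nets
   flag.
4. **Saturation flag.** `SATURATED` when the spot's saturated-pixel
   percentage strictly exceeds 10% (default). Disabled entirely when
   slides were scanned with automatic gain control (AGC), which
   guarantees no saturation; the package reports per-array saturated
   counts as a rescanning hint but treats saturation as spot-level
   exclusion, not whole-array rejection.
5. **Array QC.** For each of the three control concentrations, the CV
   (100·sd/mean, sample sd) of that control's net intensities across
   the whole array is computed — on pre-normalization nets, with
   flagged spots included, because this gate exists to catch printing
   and coating defects that flags and normalization would mask. Arrays
   whose CV for the *selected* control exceeds 20% (default) are
   discarded; the other two concentrations are evaluated and reported
   so users learn which control is the most reliable QC handle. A CV
   over a nonpositive mean is defined as +∞ and always fails.
6. **Pin-to-pin normalization** (total-intensity flavour): each block's
   spots are multiplied by `reference / block_control_mean`, where the
   reference is the mean of per-block control means over unflagged
   control spots. Blocks contain too few control spots for stable
   quantile estimation, so mean-scaling is the appropriate module
   within blocks. Blocks with no usable controls or nonpositive means
   keep factor 1 with a warning.
7. **Array-to-array normalization** (quantile flavour): each array's
   sorted unflagged control nets (three concentrations × replicas) are
   mapped onto the rank-wise mean vector across arrays by monotone
   piecewise-linear interpolation, extended by linear extrapolation of
   the outermost segments (antigen signals routinely exceed the top
   control) and floored at 0 RFU; the map is applied to every
   unflagged spot. Arrays contributing unequal control counts are
   truncated to the shortest list from the top, with a warning. The
   split of the composite normalization — means within arrays,
   quantiles between them — is the principal interpretive choice of
   this implementation and is isolated behind the `normalize` module
   interface so alternatives can be swapped in.
8. **Replicate summarization.** Per antigen and array: flagged replicas
   are dropped (reason recorded); fewer than `min_replicates` (=2)
   clean values ⇒ status `NOISY`, no mean; otherwise if the CV of the
   clean values is within 20% the mean is reported; otherwise exactly
   one value may be removed — among passing leave-one-out subsets the
   smallest-CV one wins (ties toward the larger mean) and the removed
   value is recorded as `OUTLIER`; if nothing passes the group is
   `HIGH CV`. At most one outlier is ever removed: a triplet needing
   two removals is not trustworthy data. Groups whose replicas were
   all flagged report `NOISY` (downstream convention: set `NOISY` to
   zero, drop `HIGH CV`).
9. **Consolidation.** Replicate summaries run on **normalized** values
   while flags determined on raw-vs-background signal are carried
   through: noise is a property of the raw measurement, comparability
   of the normalized one. Rows follow first appearance in the GAL;
   columns are lexicographic by array id. Cells are the mean or the
   verbatim sentinels `NOISY` / `HIGH CV`.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `noise_sd_multiplier` | 2.0 | background SDs | noise floor |
| `replicate_cv_threshold_pct` | 20.0 | % | replicate agreement gate |
| `array_cv_threshold_pct` | 20.0 | % | whole-array control gate |
| `saturation_threshold_pct` | 10.0 | % pixels | saturation gate |
| `saturation_enabled` | true | — | false for AGC-scanned slides |
| `selected_control` | MED | — | control driving array discard |
| `neighbourhood_window` | 3 | grid cells | background median patch |
| `min_replicates` | 2 | spots | fewest clean replicas for a mean |

Antigens present only in duplicate are processed with a warning rather
than rejected — the replicate mean operates on two values — so valid
data is not lost to layout thrift.

## Synthetic-slide generator

`pmarray.synth` fabricates GAL + raw files from the signal model above
with per-spot noise `signal·(1 + N(0, noise_cv)) + N(0, background_sd)`
and a 16-bit ceiling at 65535 RFU (saturation is modeled by clamping
and setting the saturated-pixel percentage). Defaults model a small
profiling experiment: 3 arrays at gains 0.5/1/2 (a 4× PMT range),
3 blocks with pin factors 0.8/1/1.25, 20 antigens in triplicate with
truths drawn uniformly from 3000–20000 RFU, a 2000/8000/24000 control
dilution series, background 500 ± 50, and 2% signal noise. Planted
artefacts: 5% of antigen spots set below the noise floor, 5% of
replicate groups given one ×5 outlier (only where the boosted value
stays below the ceiling), 2% saturated. Buffer-only filler spots sit
at background and are recorded as below-floor in the manifest.
Generation is byte-reproducible from the seed.

What the generator does **not** emulate: spatial background gradients
within blocks, intensity-dependent (non-multiplicative) bias,
carry-over between adjacent spots, morphology-driven quantification
error, or antigen-specific serum variation between arrays. Passing
recovery tests therefore demonstrates that the pipeline inverts
block/array multiplicative bias and isolates planted point artefacts —
not that it corrects spatially structured artefacts real slides can
show, which is what the manual image inspection step in array practice
remains for.

Under the default planted pin factors the whole-array control CV is
≈ 22% on every array — above the 20% default gate, by construction of
the bias being tested. Recovery fixtures therefore run with
`array_cv_threshold_pct = 30` so the normalization stages see all
arrays; the array gate itself is exercised separately on fixtures with
tight controls.

## Numerical choices

* CV uses the sample (n−1) standard deviation; CV of a nonpositive
  mean is +∞.
* All threshold comparisons strict (`<` for noise, `>` for CV and
  saturation); at-threshold values pass.
* Even-count medians are the mean of the two middle values.
* Quantile maps collapse tied source values by averaging their
  reference counterparts, keeping the map a monotone function; ties in
  sorted control vectors otherwise keep stable order.
* Outlier tie-break: equal CVs resolve toward the larger mean
  (preferring to drop the low replica, the more common dropout mode).
* Numeric output cells use Python float `repr`, which round-trips
  exactly and is locale-independent.

## Problem sizes

Tests and the acceptance script run the generator at its defaults
(3 arrays × 108 spots) and verify oracle equivalence on 200 random
grids (≤ 10×10) and 1000 random replica groups (sizes 2–6); the whole
suite completes in a few seconds on one core, and the scale is already
sufficient to exercise every code path and saturate the recovery
metrics.

## Known limitations

* The composite normalization split (means within arrays, quantiles
  between) is one defensible reading of a composite design; other
  splits would change absolute output scales though not rank structure.
* Replicate CV gating happens on normalized values while noise flags
  come from pre-normalization nets; pipelines that gate on raw nets
  will count boundary cases differently.
* The background neighbourhood is a single pass over raw values;
  iterative variants (re-filtering corrected values to convergence)
  are not implemented.
* Exactly one outlier per replicate group can be shed; larger groups
  with two bad members report `HIGH CV` rather than attempting deeper
  subset searches.
* No spatial (loess/print-tip intensity-dependent) normalization and
  no two-colour channel handling; the assay is single-channel.
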