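# Methods

## The problem

Extracellular-flux analyzers measure, per well of a 96-well plate, the
oxygen consumption rate (OCR, pmol O₂/min; mitochondrial respiration) and
extracellular acidification rate (ECAR, mpH/min; glycolytic flux) across
measurement cycles, with serial drug injections partitioning the run into
phases. Both rates are extensive quantities: they scale with the number of
cells in the well. For robust cell lines, nuclear stains give the cell
number; for loosely attached primary cells (freshly isolated intestinal
epithelium being the motivating case) staining and washing remove cells,
and efflux transporters defeat vital dyes. The package instead derives the
cell number from the pre-run brightfield image of each well.

## Cell-pixel quantification

Images are converted to a canonical 0–255 grayscale (RGB by unweighted
channel mean; integer dtypes rescaled by their dtype range; unit-scale
floats by 255). The pipeline then applies, in order:

1. **Background estimate** — Gaussian blur of the image itself. The kernel
   is normalized (constants map to themselves) and edges are replicated,
   so flat and gradient backgrounds behave predictably at the frame.
2. **Correct + invert** — `clip(background − image, 0, 255)`. Cells are
   darker than their local background in brightfield, so this single step
   is algebraically identical to "subtract background, then invert", and
   produces white objects on black. The equivalence is asserted in tests.
3. **Crop** — `floor(0.05·size)` pixels removed per side (the molded stops
   that keep the sensor off the monolayer sit at the rim on all sides, so
   the margin is taken per side, retaining the central 90% of each
   dimension).
4. **Count** — pixels with intensity strictly greater than 1 are
   "cell-pixels".

Tunable parameters (all exposed, defaults in `ImagingParams`):

| parameter | default | unit | rationale |
|---|---|---|---|
| `background_sigma` | `min(h, w)/10` | px | must be low-pass relative to single-cell size (~5–10 px at 4×) so cells vanish from the background estimate while illumination gradients survive |
| `crop_fraction` | 0.05 | per side | removes rim artifacts |
| `threshold` | 1 | 0–255 intensity | the method's detection floor; the intensity scale of the original script is not fixed by any published convention, so the threshold is a parameter with 0–255 semantics rather than hard-coded |

Degenerate inputs (images under 16×16, non-finite pixels, ≥4 channels)
are rejected, never silently processed. Counts carry a short hash of the
parameter set so any table row is traceable to its settings.

## Calibration

Standard-curve wells seeded at known densities (the supported design
space is 50,000–150,000 cells/well) give points (cell-pixels, seeded
cells) for several subjects. A quadratic `cells = a·p² + b·p + c` is
fitted by ordinary least squares with **cells as the response**: the
operational need is converting new pixel counts to cell numbers, and
fitting in that direction avoids choosing roots of an inverted quadratic.
Subjects are pooled by concatenation — one external curve serves all
plates, because image-intensity differences between plates were not found
to shift pixel counts, making in-plate standards unnecessary. The
intercept is left unconstrained (a zero intercept would be physically
motivated but is not imposed). R² = 1 − SS_res/SS_tot. Predictions are
clipped below at zero (flagged), and predictions outside the fitted pixel
range are flagged as extrapolation but not refused — sparse wells are
legitimate.

Not implemented by design: robust/weighted variants, higher-order
polynomials, per-plate curves.

## Flux metrics

The canonical schedule injects 1.5 µM oligomycin, 1 µM FCCP,
1.25 µM rotenone + 2.5 µM antimycin A, and 50 mM 2-deoxyglucose, over
12 measurement cycles of 3 min with 2 min mixing. Twelve cycles do not
divide evenly over five phases; the default allocates 4 basal cycles then
2 per post-injection phase, and the allocation is configurable through
the injection list (`first_cycle` per injection).

Per-phase summary statistics follow standard mito-stress-test practice:

- basal OCR/ECAR: mean of the last 3 pre-injection cycles (`k` configurable);
- post-injection OCR: phase extremum — minimum for the inhibitions
  (oligomycin, rotenone/antimycin, 2-DG), maximum for FCCP;
- post-injection ECAR: last-k mean with k capped at the phase length
  (default post phases have 2 cycles).

Derived metrics: ATP-linked = basal − post-OM; proton leak = post-OM −
non-mito; SRC = max − basal; 2-DG-sensitive non-mito = non-mito −
post-2-DG; oligomycin ECAR response = post-OM ECAR − basal ECAR. The
decomposition basal = ATP-linked + proton leak + non-mito is exact by
construction (verified numerically to 1e−9; floating-point subtraction
can move the last ulp). Basal OCR is reported raw; a non-mito-corrected
variant (`basal_ocr_mito`) is emitted alongside under its own name.
Phases missing from a trace yield explicit `None` metrics, never zeros.
No outlier rejection is applied within phases.

QC: wells with basal OCR below 20 pmol/min — the customary reliability
floor for this instrument class — fail QC. The boundary is inclusive
(≥ 20 passes), since it is values *below* the limit that are deemed
unreliable. Failing wells stay in per-well outputs but never enter group
statistics.

## Normalization and variation statistics

`normalized = value · reference_cells / estimated_cells`, with
`reference_cells` defaulting to the 100,000-cell plating target. Wells
with no usable image are excluded from normalized summaries rather than
back-filled from seeded counts, and non-positive cell estimates flag the
well un-normalizable.

Within-subject variation: well standard scores
`z = (well − mean)/s.d.` over that subject's QC-passing wells, with the
sample (n−1) standard deviation — the standard estimator at the 4–10
wells/subject typical of such cohorts. Because signed z-scores average to
zero identically, the subject-level summary reported is the arithmetic
mean of |z| (the raw score distribution is emitted too, so either
summary can be recomputed). Constant wells raise a defined
zero-variance error rather than returning NaN.

Between-subject variation: CV% = 100·s.d.(subject means)/mean(subject
means), sample s.d. again.

Energetic phenotype: each well maps to a basal point (basal OCR, basal
ECAR) and, when the relevant phases exist, a stressed point (max OCR,
post-OM ECAR), with quadrant labels (energetic / aerobic / glycolytic /
quiescent) relative to configurable axis midpoints.

## Synthetic data

The generators produce exactly what the parsers read, with a full ground
truth record, so every claim in the test suite is checked against known
truth.

**Images** — smooth background (constant, linear gradient, or 2-D
quadratic vignette around level 200), dark disks of uniform-random radius
(default 2–4 px) and depth 60 below background, soft-edged with a 1 px
linear falloff so thresholding near rims is exercised; overlapping cells
occlude (maximum of depth maps) rather than stack; additive Gaussian
noise, clipped to 0–255. Fixture counts are area-scaled stand-ins for
real well occupancies (tens of blobs per 256² image ↔ tens of thousands
of cells per well).

**Flux plates** — per-well cell counts are log-normal around the
100,000-cell target (strictly positive with controllable CV; default CV
25% emulates pipetting variation); each subject can carry a log-normal
rate factor (default CV 0, i.e. identical true per-cell rates across
subjects — the cleanest setting for isolating what cell-count
normalization removes). A well's noise-free trace is the default
phase-level profile — basal 100, post-OM 55, post-FCCP 160,
post-rot/AA 20, post-2-DG 12 pmol/min for OCR, with basal OCR inside the
28–110 pmol/min range seen in viable primary epithelial preparations, a
deliberately modest oligomycin response and large proton leak — scaled by
(subject factor)·(cells/100,000), plus per-cycle Gaussian noise
(default s.d. 3 pmol/min). Default cohort geometry: 7 subjects × 8 wells.

What the generators do **not** emulate: optics (defocus, vignetting
coupled to cell density, debris), instrument drift within a run, well
edge effects, or biological heterogeneity of per-cell rates within a
well. Passing tests therefore demonstrate the algorithmic contracts —
oracle equivalence, identities, estimator calibration, and the
direction and rough magnitude of variance reduction — not performance on
real plates, whose headline numbers depend on real images and animals.

The CLI's `simulate` renders images at pixel-noise s.d. 0.5, below the
counting threshold: with noise at or above the threshold a large,
density-dependent fraction of pure-noise pixels is counted, which
destroys the monotone pixel–cell relationship. Real brightfield wells
operate in the low-noise regime; the generator exposes the noisy regime
through its parameters for robustness testing.

## Numerical choices

- Gaussian blur truncated at 4σ (the library default); the oracle test
  reproduces the truncated, normalized kernel with explicit loops.
- Quadratic fit via `numpy.linalg.lstsq` (SVD); a rank check rejects
  degenerate designs; the test oracle solves the normal equations
  independently.
- Flux CSVs are written and re-read with round-trip float precision, so
  writer∘parser is the identity bit-for-bit.
- Ties in phase extrema resolve to the extremal value itself (indices are
  never needed downstream).
- All randomness flows through `numpy.random.default_rng(seed)`;
  fixed-seed outputs are byte-identical, which the end-to-end test
  asserts across two full CLI runs.

## Problem sizes in the validation suite

Oracle sweeps use 50 random images (64²–512²); identity checks use 1,000
random traces; estimator calibration uses 1,000 replicates; the
variance-reduction study uses 200 cohorts of 7 subjects × 8 wells. These
sizes give the binomial/standard-error margins quoted in the tests while
keeping the whole suite in the tens of seconds.

## Known limitations

- The cell-pixel count saturates as cells overlap; the quadratic
  calibration absorbs mild saturation but the method is not designed for
  confluent or stacked cultures.
- Threshold semantics assume the 0–255 scale; images quantized to very
  few gray levels will step coarsely.
- The z-score and CV machinery assumes ≥2 wells/subject and ≥2 subjects;
  degenerate cohorts raise typed errors by design.
- Group hypothesis testing is out of scope; outputs are descriptive
  summaries meant for downstream statistics.
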