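# Methods

This note documents the models, parameter choices and numerical
conventions behind each analysis, and what the synthetic generators do
and do not emulate.

## Tether force (membrane-tension proxy)

A bead held in an optical trap behaves as a harmonic probe: the force on
a membrane tether equals the trap stiffness k (pN/nm) times the bead's
displacement from the trap centre Δx (nm). Tether force is proportional
to apparent plasma-membrane tension and is used here purely as that
proxy; tether radius and bending-rigidity estimation are out of scope.

**Measurement.** The reported force is the mean force over the 1 s
immediately preceding the first stage manipulation after tether
formation, minus the mean over the zero-reference window (the interval
in which the cell is moved toward the bead, relaxing the tether). A
0.2-s settling margin after the toward-cell event excludes stage-motion
transients; both spans are configurable. Because the baseline is
subtracted, the measurement is exactly invariant to any constant
displacement offset (detector drift).

**Calibration.** The protocol calibrates stiffness per experiment but
leaves the method open; equipartition is implemented — each quadratic
degree of freedom of the trapped bead carries kB·T/2, so
k = kB·T / var(x) over a tether-free segment (>= 1000 samples required;
kB = 1.380649e-2 pN·nm/K). Direct stiffness input is also accepted.
At 1e4 samples the sampling error of the variance (~sqrt(2/n) ≈ 1.4%)
keeps the calibration within 5% of truth.

**QC rules.**

* *stale_tether*: the plateau window ends more than 30 s (configurable)
  after tether formation — actin polymerises into older tethers and
  corrupts the reading.
* *double_tether*: occasionally one bead pulls two tethers, doubling the
  force. Flagged when a measurement lies within 15% (configurable) of
  twice the median of the same cell's other unflagged measurements;
  candidates are examined largest-first, and an external annotation
  (from DIC inspection) always takes precedence. The 2x signature is the
  only quantitative criterion available; visual identification cannot be
  reproduced in code.
* *no_zero_reference*: traces lacking the toward/away event pair fall
  back to a changepoint proposal (lowest rolling mean) and carry this
  flag; flagged measurements are excluded from summaries.

**Relative force.** To pool experiments, each unflagged force is divided
by the mean unflagged interphase force of the same experiment; the
interphase values of an experiment then average to exactly 1. Zero
reference is applied per tether (per trace), the natural unit of
measurement here.

**Synthetic traces** are plateau/step signals with i.i.d. Gaussian
displacement noise — the simplest stationary model of trap thermal
noise, with SD exposed as a parameter since the instrument's noise level
is setup-specific. Stage events are encoded explicitly (the stage is
computer-controlled, so events are known at acquisition time). The
default schedule (tether at 0.5 s, toward at 6 s, away at 11 s, 12 s
duration at 5 kHz) gives a 1-s plateau window and a ~4.8-s baseline
window, so baseline noise contributes little to the measured force. Not
emulated: bead-tracking artefacts, low-frequency drift other than a
constant offset, tether rupture, or full Brownian dynamics.

## LFQ proteomics of clathrin-coated-structure fractions

Protein-group LFQ intensities from paired interphase/mitotic
preparations over E experiments (E = 4 typically). Contaminant/decoy
rows (`CON__`/`REV__` prefixes) are dropped with a logged count.

**Ratio.** Per condition, the combined-analysis LFQ column is used when
present; otherwise the mean over nonzero per-experiment values (robust
to dropout). Ratio = interphase/mitotic; aggregation happens before
division. Proteins with a zero on either side are excluded from the
ratio analysis (`excluded_zero`); when the nonzero side exceeds 1e6 LFQ
units the protein is instead classified condition-exclusive — large
signal in one condition and none in the other is more plausibly genuine
all-or-nothing regulation than detection failure.

**Gaussian null.** Most proteins are not regulated between conditions,
so the log2-ratio histogram is dominated by a single Gaussian. A curve
amp·exp(−(x−mu)²/2sigma²) is least-squares fitted to the bin counts
(default bin width 0.25 log2 units, chosen to give >= 30 bins over a
typical ±4 range; Freedman–Diaconis available), initialised at the
sample moments; `method="moments"` bypasses the fit. Outliers are
proteins with log2 ratio strictly beyond mu ± 2 sigma (the boundary has
measure zero; strictness is documented for reproducibility). Degenerate
input (zero spread) or non-convergence raises an error carrying the
moment estimates. The rule is stated in sigma units, so sigma — not
variance — enters the bounds.

**Per-experiment consistency** reruns the ratio → fit → call chain on
each experiment's columns alone and reports each experiment's outlier
set, their intersection, and per-protein counts; experiments with < 50
usable ratios are skipped with a warning. Under a pure null ~4.55%
(2·Φ(−2)) of proteins are flagged per experiment and the intersection is
empty with high probability.

**Synthetic tables.** Intensities are log-normal (positive,
heavy-tailed). Each protein draws a base abundance (ln-SD 1.0) and each
experiment a loading factor (ln-SD 0.25) *shared between the two
condition channels of that experiment*; the protein's ratio multiplies
the interphase channel. The realised ratio therefore equals the drawn
ratio exactly, which is what the null model asserts; per-experiment
deviation can be added via `experiment_scatter` when imperfect
reproducibility is wanted. Dropout injects zeros uniformly at a default
5% rate. Not emulated: peptide-level effects, match-between-runs,
intensity-dependent missingness, or cross-run normalisation biases.

## Image quantification

Equatorial confocal sections of rounded (mitotic) cells are modelled as
discs with an annular cortex. The measurement ROIs follow the manual
convention: a 24-px-wide ring inside the cell border (mask minus its
erosion by a 24-px disc — the ring lies inside the outline) and a
50x50-px cytoplasm box. The box is placed at the pole of the mask's
distance transform, the reproducible analogue of manual placement
farthest from the border; avoiding nucleus contamination, where
relevant, is the caller's responsibility via a provided mask. Masks are
derived as the largest connected component above an Otsu threshold with
holes filled, unless a mask is supplied (it then takes precedence). From
z-stacks, the equatorial plane is the one maximising mask area.

Background is the median intensity outside all (slightly dilated) cell
masks — median for robustness to stray cells. With b the background:

* F-actin cortical enrichment = (mean_ring − b) / (mean_box − b);
* cytoplasmic G-actin = mean_box(G channel) − b;
* transferrin uptake (raw) = sum over the mask of max(I − b, 0) —
  integrated internal signal, meaningful because surface transferrin is
  acid-stripped in the assay; normalized uptake divides by the mean raw
  uptake of an explicitly designated reference group (the reference is a
  required argument because different experiments normalise to different
  groups).

Both the ratio and raw uptake are exactly invariant to uniform additive
offsets on noiseless images. The synthetic generator's default cortical
band width equals the ring ROI width (24 px), so the ring samples pure
cortex and the generator truth (cortex−b)/(cytoplasm−b) is the quantity
the analysis estimates. Not emulated: non-circular cells, nuclei,
intensity gradients, camera shot noise (noise is additive Gaussian), or
out-of-focus light — recovery results bound ROI/segmentation error, not
these real-world effects.

## Flow cytometry

Events with forward scatter below 200 detector units are sub-cellular
debris and are removed (gate inclusive at the boundary: FSC >= 200 kept).
The per-sample statistic is the geometric mean of FL1,
exp(mean(ln FL1)), the standard summary for log-normal fluorescence;
non-positive FL1 events are unmeasurable on a log scale and are excluded
with a reported count. Inputs are treated as linear detector values.
CSV column tables are the core format; FCS parsing is out of scope.
Synthetic samples are mixtures of Gaussian-FSC / log-normal-FL1
populations plus uniform sub-gate debris; spillover and compensation are
not modelled.

## Group statistics

Summaries are mean ± SEM (SEM = sample SD/sqrt(n)). The two-sample
t-tests accept raw values or printed (mean, SEM, n) summaries — the t
statistic is a function of those summaries, so both paths agree exactly.
The default variant is Welch (Satterthwaite df): the tension groups'
variances differ several-fold, and the Welch computation from the
printed summaries reproduces the published p = 0.027; Student's t is
available by flag and is the named test for the relative-force
comparisons. Multi-group comparisons use one-way ANOVA with Tukey's HSD
(scipy's studentized-range implementation); Tukey requires raw values
because the adjustment needs within-group spread, and a reference-group
filter is provided for "comparison to control" figures. All p-values are
two-sided. Zero-variance degenerate inputs: equal means give p = 1 by
convention, unequal means are an error.

## Problem sizes and determinism

Every generator is deterministic given its spec (seed included). The
validation suite uses 50 traces for force recovery, 20 segments for
calibration, 5000 + 20 proteins for null calibration and outlier
sensitivity, 100 cells for ratio recovery, and 1000 simulations for
ANOVA type-I calibration — sizes at which the Monte-Carlo error of each
checked quantity is several-fold smaller than its acceptance band.
`scripts/acceptance.py` recomputes all of them from a single seed.

## Known limitations

* The double-tether rule cannot flag a cell measured only once at 2x
  force; the annotation override exists for that case.
* The changepoint fallback for missing zero-reference events assumes the
  dip is the lowest-mean window; sloped drift can fool it (hence the QC
  flag rather than silent acceptance).
* The Gaussian-null fit assumes a unimodal null; a strongly bimodal
  ratio distribution would need mixture modelling.
* Image quantification assumes one dominant cell per field; multi-cell
  fields need provided masks.
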