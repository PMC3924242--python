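# mitocme

Quantitative analysis pipeline for studying the **mitotic shutdown of
clathrin-mediated endocytosis (CME)** — the observation that cells stop
internalising transferrin and other clathrin cargo during early mitosis,
while membrane tension rises and the actin cytoskeleton is sequestered
into a stiff rounded cortex.

The package re-implements, as tested reusable code, the five quantitative
assays such a study rests on, plus a synthetic-data module that generates
every input type with known ground truth so the whole pipeline can be
validated without any experimental download:

| module | measurement |
| --- | --- |
| `mitocme.tether` | optical-trap **tether force** (membrane-tension proxy): force = trap stiffness k (pN/nm) x bead displacement Δx (nm); 1-s plateau average minus a stage-driven zero reference, with stale-tether (> 30 s), double-tether (2x rule) and missing-zero QC flags, and per-experiment relative forces |
| `mitocme.proteomics` | **LFQ ratio analysis** of clathrin-coated-structure fractions: per-protein interphase/mitotic ratio, Gaussian fit to the log2-ratio histogram, outliers at mu ± 2 sigma, condition-exclusive classification (> 1e6 vs 0) |
| `mitocme.imaging` | **ROI image quantification**: 24-px border ring and 50x50 cytoplasm box, background-subtracted cortex/cytoplasm F-actin ratio, cytoplasmic G-actin mean, integrated transferrin uptake normalized to a reference group |
| `mitocme.flow` | **flow cytometry**: FSC gate at 200 (debris exclusion), FL1 geometric mean per sample |
| `mitocme.stats` / `mitocme.report` | Student/Welch t-tests (raw values or printed mean ± SEM summaries), one-way ANOVA with Tukey HSD, mean ± SEM panels |
| `mitocme.synthetic` | generators for all of the above with recorded ground truth |

Intended users: membrane-biophysics and endocytosis labs wanting a
scripted, reproducible version of these otherwise manual analyses, and
anyone needing calibrated synthetic data for them.

## Worked example

```python
from mitocme import synthetic, tether, stats
from mitocme.proteomics import CcsRatioModel, read_protein_groups
from mitocme.synthetic import LfqGenSpec, OutlierSpec, TraceGenSpec

# --- tether force from a synthetic trace (27 pN ground truth) ---
trace, truth = synthetic.gen_tether_trace(
    TraceGenSpec(true_force=27.0, noise_sd=10.0, seed=0), phase="metaphase")
m = tether.measure_tether_force(trace)
print(f"measured {m.force:.2f} pN (truth {truth} pN), flags={sorted(m.qc_flags)}")

# --- LFQ ratio analysis with two injected outliers ---
table, _ = synthetic.gen_lfq_table(LfqGenSpec(
    n_proteins=1000, seed=0, dropout_rate=0.0,
    outlier_specs=(OutlierSpec("CTTN", 46.2), OutlierSpec("NSF", 0.077))))
res = CcsRatioModel(read_protein_groups(table)).fit()
print(res.summary())

# --- Welch t-test straight from printed mean ± SEM summaries ---
r = stats.two_sample_t((19.2, 1.5, 13), (27.0, 2.8, 11))
print(f"Welch t = {r.statistic:.3f}, df = {r.df:.1f}, p = {r.p_two_sided:.4f}")
```

prints

```
measured 27.01 pN (truth 27.0 pN), flags=[]
Interphase/mitotic LFQ ratio analysis
=============================================
protein groups analysed : 1002
  ratio_ok              : 1002
  excluded_zero         : 0
  interphase_exclusive  : 0
  mitotic_exclusive     : 0

Gaussian null (log2 ratio histogram, bin 0.25):
  mu = 0.1947, sigma = 0.7861  (outlier bounds -1.377 .. 1.767)
  fit r^2 = 0.9936 over 38 bins

outliers: 24 interphase-enriched, 24 mitotic-enriched
  strongest (by |log2 ratio|):
    CTTN         ratio   46.200 log2   5.530  interphase_enriched
    ...
    NSF          ratio    0.077 log2  -3.699  mitotic_enriched

Welch t = -2.456, df = 15.5, p = 0.0263
```

The tether force is recovered to within the thermal-noise limit of the
1-s averaging window; the Gaussian null fitted to 1000 synthetic null
proteins returns the generating (mu, sigma) ≈ (0.2, 0.8); the two
injected ratio anchors — a cortactin-like protein 46.2-fold enriched in
interphase fractions and an NSF-like protein accumulating in mitotic
fractions (ratio 0.077) — fall far outside mu ± 2 sigma and are called in
the right directions; and the Welch test computed purely from the printed
interphase (19.2 ± 1.5 pN, n = 13) vs metaphase (27 ± 2.8 pN, n = 11)
summaries gives p = 0.026, matching the published comparison (p = 0.027).

A `mitocme` console script exposes the same pipeline on files:
`mitocme simulate {trace|lfq|image|flow}`, `mitocme tether`,
`mitocme lfq`, `mitocme imagequant`, `mitocme flow`, `mitocme report`
(see `mitocme --help`).

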