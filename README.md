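# eptools — energy proxy trait phenomics for embryo video

`eptools` implements untargeted spectral phenotyping of developing embryos
from time-lapse video, as used to compare the thermal sensitivity of
freshwater gastropod embryos (*Lymnaea*, *Radix*, *Physella*-like systems)
across their whole development.

The core idea: instead of measuring named traits, reduce each 30-s clip of
an embryo to the mean pixel brightness of a bounding box per frame, and
decompose the fluctuations of that series with Welch's method into an
**energy proxy trait (EPT)** — the vector of signal energy in 60
temporal-frequency bands, band *k* covering [0.1 k, 0.1 (k+1)) Hz up to
6 Hz. Everything the embryo does that moves pixels (ciliary rotation,
body flexing, heartbeat, radula rasping) lands at its own characteristic
frequencies, so the EPT spectrum is an integrative, stage-transferable
phenotype. **Total energy** (the sum over all 60 bands) proxies gross
rates of physiology and behaviour.

On top of the spectra the package provides the comparative machinery:

* **Relative developmental time** — each embryo's clip times are rescaled
  by its own hatch time onto [0, 1], and the four manually scored event
  onsets (ciliary rotation, heartbeat, crawling, radula) delimit
  *physiological windows* in that embryo's own event order — so
  heterochronic species (Physidae crawl before their heart beats;
  Lymnaeidae the reverse) are compared window by window, not hour by hour.
* **Trajectory comparison** — a repeated-measures ANOVA of cohort-mean
  total-energy trajectories on a 100-point relative-time grid (df (1, 99)),
  with per-gridpoint Tukey HSD post hoc tests reported as contiguous
  significant regions of developmental time.
* **Band-wise comparison** — one Kruskal–Wallis test per frequency band on
  per-embryo window means, Bonferroni-controlled at α/60 (0.05/60 ≈ 0.00083).
* **Ordination** — PCA of log10 band energies (per-embryo window means)
  with a deterministic sign convention, plus attribution of each axis to
  the frequency bands that drive it and the groups it separates.
* **Synthetic embryo generator** — raw study video is rarely shareable, so
  the package ships a generator producing event itineraries, band-limited
  luminance traces and (optionally) full 8-bit frame stacks with known
  ground truth, including configurable temperature effects on timing,
  amplitude and frequency. Every stage of the pipeline is testable against
  it without any download.

## Worked example

```bash
ept demo --out scratch/demo --seed 2 --n 4
```

runs the whole pipeline on a small synthetic two-temperature experiment
(4 embryos per cohort, physid event order, 25 °C cohort accelerated ×0.75
with ×1.3 signal amplitude) and prints:

```
trajectory F(1,99)=194.98, p=3.91e-25
window rotation: significant bands none
window heart: significant bands none
window crawling: significant bands none
window radula: significant bands none
event rotation: accelerated (H=5.33, p=0.0209)
event heart: accelerated (H=5.33, p=0.0209)
event crawling: accelerated (H=5.33, p=0.0209)
event radula: accelerated (H=5.33, p=0.0209)
event hatch: accelerated (H=5.33, p=0.0209)
PC1-3 cumulative variance: 66.21%, 86.85%, 97.22%
```

Read: the warm cohort's total-energy trajectory differs strongly
(F(1, 99) — temperature paired across the 100 relative-time grid points);
no single band reaches the Bonferroni threshold 0.00083 at n=4 embryos per
group (the rank test cannot get that low until n≈8 per group — direction
and magnitude are still written to `bandwise.csv`); all four event onsets and hatch
are earlier in the warm cohort (with n=4 the best attainable p is 0.02);
and three principal components carry ~97% of the log-spectral variance.
Full tables land in `scratch/demo/analysis/`, the generated cohort in
`scratch/demo/data/`, and every stage writes a manifest with its settings
and seed.

The same analysis is available as a library:

```python
from eptools import ExperimentConfig, run_experiment
result = run_experiment(ExperimentConfig(n_per_cohort=20), rng_seed=1)
result.trajectory.F, result.bandwise["heart"].hz_ranges
```

and the spectral step composes with scikit-learn
(`BandEnergyExtractor` → `LogSpectraPCA` in a `Pipeline`).

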