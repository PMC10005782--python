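# mtkymo

Microtubule dynamic-instability simulation and kymograph-based dynamics
quantification.

Microtubules stochastically switch between growth, shrinkage and pause —
dynamic instability — and kinetochore proteins such as the *C. elegans*
BUB-1 / HCP-1/2 / CLS-2 module tune the switching rates.  In vitro this is
measured by TIRF microscopy: microtubules polymerize from GMPCPP-stabilized
seeds, two-channel movies (lattice and seed) are acquired every 3 s for
20 min, kymographs are drawn along each microtubule, and the tip trace is
read off as growth slopes, pause plateaus and shrinkage drops.  `mtkymo`
implements that entire workflow as tested, scriptable code, for people who
analyze such assays or need a calibrated synthetic benchmark for tip-tracking
pipelines:

* **`mtkymo.model`** — a three-state continuous-time Markov model of the
  plus end (growth G, pause P, shrinkage S; rates `k_gs, k_gp, k_pg, k_ps,
  k_sg, k_sp` in min⁻¹, speeds `v_g`, `v_s` in µm/min), sampled exactly
  (event-driven), with seed-boundary truncation and renucleation at rate
  `k_nuc`; trajectory discretization on the camera frame grid; two-channel
  kymograph rendering (PSF blur, background, camera noise); and the
  closed-form long-run statistics (stationary occupancies π solve πQ = 0)
  used as oracles.
* **`mtkymo.kymo`** — kymograph construction from movie stacks, sub-pixel
  tip detection, phase segmentation (velocity thresholding with
  least-squares changepoint refinement, sub-frame event recovery), and
  grouping of segments into per-microtubule lifetimes.
* **`mtkymo.stats`** — whole-lifetime statistics: catastrophe frequency
  `f_cat` = catastrophes per growth-excursion time (pauses interleaved in an
  excursion included, shrinkage excluded), rescue frequency `f_res` =
  rescues per time spent shrinking, percent time in pause, time-weighted
  growth rate; condition aggregation (mean/SD/SEM plus pooled frequencies)
  and many-to-one comparisons (Dunnett, ANOVA/Kruskal–Wallis with Holm,
  unpaired t, max-|t| permutation).
* **`mtkymo.assays`** — spindle density (integrated intensity / mean
  background on sum projections of 4 z-planes, 45 s before anaphase
  onset), spindle area, kinetochore linescan ratios, and embryonic
  viability (L4/adults divided by eggs/L1).
* **`mtkymo.io` / `mtkymo.cli`** — tidy CSV schemas with unit-bearing
  headers and row-count guards, TIFF rasters with calibration sidecars,
  measurement-workbook ingestion via an explicit column map, and an
  `mtkymo` command with `simulate`, `segment`, `summarize`, `compare`,
  `quantify-spindle`, `quantify-linescan`, `viability` and `make-fixtures`
  subcommands.

See `docs/methods.md` for the model, the estimator design and its
limitations.

## Worked example

Simulate a control condition and a pause-promoting condition (pause-entry
rates ×25, pause-exit rates ÷2 — the signature of the assembled kinetochore
module on the lattice), push both through the full image pipeline at a
lattice signal-to-noise ratio of 10, and compare:

```python
from mtkymo import model, pipeline

control = model.BASELINE_PARAMS
module = model.bhc_like(control)          # pause-entry x25, pause-exit /2
optics = model.OpticsConfig(noise_sigma=10.0)

ctrl = pipeline.condition_summary(
    model.simulate_condition(control, 60, 1200.0, master_seed=21),
    "control", route="image", master_seed=21, optics=optics)
mod = pipeline.condition_summary(
    model.simulate_condition(module, 60, 1200.0, master_seed=22),
    "module", route="image", master_seed=22, optics=optics)

for cond in (ctrl, mod):
    print(cond.label, cond.stats.loc["pause_pct", ["mean", "sem"]].round(3).to_dict())
print("fold change:",
      round(mod.stats.loc["pause_pct", "mean"] / ctrl.stats.loc["pause_pct", "mean"], 1))
```

Output:

```
control {'mean': 2.02, 'sem': 0.548}
module {'mean': 50.002, 'sem': 2.139}
fold change: 24.7
```

Each microtubule spends ~2% of its lifetime paused under control
conditions; the pause-promoting rate set raises that to ~50%, a ~25-fold
increase measured entirely from rendered kymographs — the synthetic
counterpart of the strong synergistic pause promotion seen when the full
kinetochore module decorates microtubules.

The same analysis from a shell:

```sh
mtkymo simulate --n-mt 60 --duration 1200 --seed 21 --condition control --out control.csv
mtkymo segment  --traces control.csv --condition control --out control-segments.csv
mtkymo summarize --segments control-segments.csv --out control-summaries.csv
# ... repeat for other conditions, then:
mtkymo compare --summaries all-summaries.csv --reference control \
               --method dunnett --alpha 0.01 --out comparison.csv
```

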