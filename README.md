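# sc2wb — subcellular single-cell western blot quantification

`sc2wb` is an analysis pipeline for **subcellular single-cell western blots
((sc)²WB)**: microwell-array electrophoretic immunoassays that resolve, for
every individual cell, how much of a protein sits in the cytoplasm versus the
nucleus. The assay isolates single cells in microwells molded into a
polyacrylamide gel, lyses the cytoplasm and the nucleus sequentially with
differential detergent buffers, and runs the two lysates along the same axis
in opposite polarities (*bi-directional PAGE*), so each well owns a short
separation lane with cytoplasmic bands "east" of the well and nuclear bands
"west". The package is aimed at analysts quantifying such scans (or
benchmarking quantification methods): it turns multi-channel TIFF array scans
into per-cell band tables, localization fractions, separation-quality metrics
and population statistics, and ships a physics-grounded simulator that
generates realistic scans with exact ground truth.

## What it computes

For each lane profile (transverse sum of the lane, background subtracted
using the band-free lane flanks), protein bands are fit as Gaussians
A·exp(−(u−x)²/2σ²). A band is **called** when

- SNR = A / σ_background > 3, and
- R² of the fit > 0.7,

and quantified by its area under the curve over the peak width **w = 4σ**,
i.e. the trapezoidal integral of the profile over [x−2σ, x+2σ]. Localization
follows directly from band geometry:

- **Nuc = AUC_nuclear / AUC_total**, **Cyt = AUC_cytoplasm / AUC_total**
- expression is reported mean-normalized (AUC/AUC_mean) and max-normalized
  (AUC/AUC_max)

Separation quality uses the standard metrics **R_S = (x₁−x₂)/(0.5(w₁+w₂))**
(resolution of adjacent peak pairs), **n_c = L/w** (peak capacity with the
widest called peak, L = 1 mm total axis), and the migration-distance CV
across the array. Populations of per-cell metrics are summarized
nonparametrically: median ν, IQR = Q₃−Q₁, and the nonparametric skew
**S = (μ−ν)/σ**. Transport scaling in the simulator follows **τ = x²/2D**
(diffusion timescale) and diffusive band broadening σ(t) = √(σ₀²+2Dt).

## Layout

- `src/sc2wb/` — the library: `layout` (geometry, TIFF I/O, lane profiles),
  `peaks` (Gaussian fitting, peak calling, 4σ AUC), `localize` (fractions,
  R_S, n_c, migration CV), `stats` (nonparametric summaries, replicate CV,
  cross-modality correlation, time course), `simulate` (synthetic scans +
  ground truth), `scenarios` (canonical benchmark conditions), `pipeline` +
  `cli` (configured runs).
- `analysis/01…05_*.py` — numbered narrative drivers (transport scaling,
  localization panel, separation quality, translocation time course,
  technical variance); each writes a table under `results/`.
- `examples/nfkb_scenario.yaml` — a complete run configuration.

## Worked example

```bash
python analysis/02_localization_panel.py --seed 1
```

simulates the validation panel (two nuclear and two cytoplasmic
single-compartment targets, plus a partially solubilized organelle target),
quantifies every lane and prints:

```
      target compartment  n_cells fraction_reported  mean_pct  sd_pct  true_mean_pct
     laminAC     nuclear       32           nuclear    100.00    0.00         100.00
   histoneH3     nuclear       22           nuclear    100.00    0.00         100.00
    TurboGFP cytoplasmic       32       cytoplasmic    100.00    0.00         100.00
beta-tubulin cytoplasmic       32       cytoplasmic    100.00    0.00         100.00
       mtGFP       mixed      103       cytoplasmic     79.76   10.57          79.71
```

Single-compartment targets report 100.0 ± 0.0% localization to their own
compartment — bi-directional PAGE physically separates the fractions, so
there is no cross-talk — while the organelle-associated target recovers its
partial (~79% cytoplasmic) solubilization, matching the simulated truth
(79.71%) well within sampling error.

The same thing as a configured CLI run (simulate → quantify → stats):

```bash
sc2wb all -c examples/nfkb_scenario.yaml -o results/nfkb_run --seed 1
# time-to-peak: 60.0 min -> results/nfkb_run
```

which writes per-timepoint scans, `peaks.csv` / `cells.csv` / `metrics.csv`,
a population `summary.json` and a provenance manifest.

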