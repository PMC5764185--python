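# Methods

## The measurement model

A subcellular single-cell western blot array places one cell per microwell
(32 μm diameter, 40 μm deep; 1 mm pitch along the separation axis, 0.25 mm
transverse) in a thin polyacrylamide gel. Two interspersed PAGE runs of
opposite polarity move the cytoplasmic lysate "east" of the originating well
and the nuclear lysate "west", so a single 1 mm lane per cell (±500 μm about
the well center) carries both compartments, spatially indexed. Fluorescence
scans of the immunoprobed gel are therefore analyzed lane by lane:

1. **Lane extraction** (`layout`). Lanes are located from the fabricated
   geometry, not detected: each well owns a rectangle spanning
   ±`separation_length_per_side` axially (half-open at the east edge so
   adjacent lanes tile exactly at `separation_length_per_side =
   pitch_axis/2`) and one transverse pitch across. The lane is collapsed to
   an axial profile by a transverse **sum** (preserves total signal; mean
   optional). Background is the median of the outermost 10% of axial pixels
   on each end — assumed band-free because bands migrate mid-lane — and the
   noise scale is the robust s.d. (1.4826·MAD) of those flanks. Axial
   coordinates are signed micrometers, 0 at the well center, east positive;
   scans with the opposite physical orientation are flipped on extraction so
   downstream code sees one convention.

2. **Band fitting and calling** (`peaks`). Candidate maxima on each signed
   half-lane (the ±16 μm well interval is excluded) come from
   `scipy.signal.find_peaks` with prominence 2× the background s.d.; each
   candidate is fit as a Gaussian by unbounded Levenberg–Marquardt least
   squares with an analytic Jacobian (initial values: profile maximum,
   half-max width / 2.355; ties between equal maxima break toward smaller
   |x|). Candidates whose centers overlap within 2σ are refined jointly as a
   multi-Gaussian. Non-convergence yields an uncalled, flagged candidate,
   never an exception. A candidate is **called** when SNR = A/σ_bg > 3 and
   R² > 0.7 (R² against the window mean, window = candidate ±3 initial σ),
   with one additional resolvability requirement: the fitted σ must be at
   least one pixel spacing, since no physical band (injected width ≈ well
   diameter/4, then diffusively broadened) can be narrower than the sampling
   grid. This keeps the false-call rate on noise-only lanes below 1% while
   leaving real bands (σ ≈ 20–60 μm vs. 5 μm pixels) untouched.

3. **AUC** (`peaks.auc_4sigma`). The peak width for area analysis is w = 4σ:
   the AUC is the trapezoidal integral of the measured background-subtracted
   profile over [x−2σ, x+2σ] (window edges interpolated onto the pixel grid,
   negative integrand floored at 0, clipped to the lane). This window holds
   erf(√2) = 95.45% of a Gaussian's mass, a property the tests use as an
   analytic oracle. A config flag switches to the fitted curve's analytic
   area over the same window; raw integration is the default because it is
   robust to mild shape misfit.

4. **Localization** (`localize`). Called-peak AUCs are summed per side;
   Nuc = AUC_west/AUC_total and Cyt = AUC_east/AUC_total under the default
   orientation (east = cytoplasmic; the flag `east_is_cytoplasmic` flips the
   mapping because scan orientation conventions vary). A side with no called
   peak contributes 0; a cell with no called peak at all is flagged "not
   detected" and excluded from population fractions. Bands whose 4σ window
   overlaps the well are flagged *well-straddling* and excluded from both
   fractions rather than split — there is no principled splitting rule for a
   band sitting on the well.

5. **Separation quality** (`localize`). R_S = |x₁−x₂| / (0.5(w₁+w₂)) for
   adjacent called-peak pairs (signed positions, so an east/west pair
   measures the full bi-directional spacing); peak capacity n_c = L/w_max
   over called peaks (conservative: widest peak); migration CV uses each
   cell's dominant (largest-AUC) called band so faint secondary artifacts
   cannot inflate the uniformity estimate. All CVs use the sample (n−1) s.d.

6. **Population statistics** (`stats`). Median, quartiles by linear
   interpolation between order statistics (NumPy's default, the "type 7"
   rule — recorded here because quartile conventions change IQR by up to
   0.5 on the integer test fixture), IQR = Q₃−Q₁, nonparametric skew
   S = (μ−ν)/σ (positive for right-heavy tails), CV = 100·σ/μ. Replicate
   variation is the CV of a chosen summary field across replicate
   devices/wells. Cross-modality agreement is the Pearson correlation of
   paired per-timepoint medians (Spearman by flag; the default is Pearson
   because the comparison is between two estimates of the same quantity on
   the same scale) plus an OLS fit with 95% CIs via statsmodels. Time-to-peak
   is the timepoint maximizing the median nuclear fraction, earliest on ties
   (a conservative onset estimate); timepoints with <2 detected cells are
   excluded with a warning.

## The simulator

`simulate` renders what the scanner would see, plus exact truth, so every
pipeline stage can be scored against known parameters.

Per cell and target: total band area AUC_total ~ lognormal with configurable
mean and CV; nuclear fraction ~ normal(mean, sd) clipped to [0,1] (Beta with
matched moments optional); the east/west split is
AUC·(1−f_nuc) / AUC·f_nuc, each scaled by (1−loss). Bands are Gaussian
axially — centered at ±(drift_velocity·t_page), per-cell migration perturbed
with a configurable CV — and uniform across the well-diameter worth of
transverse rows, normalized so the transverse-summed profile integrates to
the intended AUC (the conservation property tested to <0.5%). Additive
Gaussian noise models scanner read noise. Identical seeds give bit-identical
images and truth tables.

Default parameters (changed only via configuration, never per analysis):

| parameter | default | basis |
|---|---|---|
| well diameter / depth | 32 / 40 μm | device geometry |
| pitch (axis / transverse) | 1000 / 250 μm | device geometry |
| separation length | 500 μm per side (L = 1 mm) | device geometry |
| pixel size | 5 μm/px | typical microarray-scanner setting; no value is dictated by the assay |
| E, t_page, t_lysis | 40 V/cm, 17 s, 25 s | standard run conditions |
| σ₀ | 8 μm (well diameter/4) | injection plug width |
| D (in-gel, band broadening) | 15 μm²/s | sieving gel slows proteins ~6× below free solution (D_GFP = 88 μm²/s, which governs *microwell* transport, not in-gel broadening); gives w ≈ 96 μm and n_c ≈ 10 on the 1 mm axis, the observed separation quality |
| drift velocity | 250/17 μm/s | mid-lane migration in one PAGE step |
| migration CV | 6.4% | observed electromigration uniformity across arrays |
| expression CV | 0.4 | typical single-cell protein expression spread; lognormal keeps AUCs positive |
| nuclear-fraction sd | 0.11 | observed cell-to-cell localization spread for a partially solubilized target |
| mean AUC / noise sd | 5×10⁵ AU·μm / 10 AU | arbitrary AU scale; yields band SNR ≈ 10² at the profile level, comfortably above threshold, with low expressers still detectable |
| diffusive loss | 1 − exp(−t_lysis/τ_loss), off by default | the loss phenomenon is physical (open wells leak lysate by diffusion) but its functional form is not established; a single exponential with configurable τ_loss is the simplest saturating model |

The translocation scenario uses a Gaussian pulse in stimulation time
(baseline 0.15, amplitude 0.45, peak 60 min, width 25 min) as a generic
unimodal import/export transient; it is not a mechanistic NF-κB model.

**What the simulator does not emulate:** spatially varying background and
flat-field structure, band asymmetry (injection tailing, thermal gradients),
Poisson shot noise (optional hook, off by default), antibody off-target
binding, probe stripping efficiency, molecular-mass-dependent mobility (each
target's migration distance is configured, not derived from a ladder), and
nuclear-pore leakage of small proteins. Passing recovery tests therefore
demonstrates that the quantification is correct *given* Gaussian bands with
additive noise — the assay's own premise — not that it is robust to every
real-scan artifact.

## Problem sizes

Benchmarks use the study-scale conditions throughout: 32 (and 22) cells for
single-compartment localization, 103 cells for the partial-organelle
fraction, 44 cells for the four-target multiplexing panel, 187 cells for
migration uniformity, and 9 timepoints × 100 cells for the translocation
time course. A full time-course run (simulate + quantify 900 lanes) takes
~10 s on one CPU.

## Known limitations

- Multiplexed channels are demixed by nearest expected migration distance;
  co-migrating targets in one channel are not deconvolved beyond the joint
  multi-Gaussian refinement of overlapping candidates (>2 overlapping bands
  per side are not modeled).
- AUC integrates measured signal, so heavily overlapping bands double-count
  shared window area; the fitted-curve AUC option avoids this at the cost of
  shape-model dependence.
- No absolute (molar) calibration is attempted: AUCs are arbitrary
  fluorescence units, meaningful as ratios and normalized expression only.
- Wells are trusted from the layout; a misregistered scan (origin offset)
  will silently shift every lane — registration is out of scope.
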