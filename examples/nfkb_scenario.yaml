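# NF-kB-like translocation time course: simulate, quantify and summarize with
#   sc2wb all -c examples/nfkb_scenario.yaml -o results/nfkb_run --seed 1
layout:
  n_rows: 10
  n_cols: 10
  well_diameter: 32.0      # um
  well_depth: 40.0         # um
  pitch_axis: 1000.0       # um along the separation axis
  pitch_transverse: 250.0  # um across
  separation_length_per_side: 500.0  # um
  pixel_size: 5.0          # um per pixel

panel:
  - name: NFkB
    channel: AF647
    mean_auc: 500000.0         # AU*um, population mean band area
    expression_cv: 0.4         # lognormal cell-to-cell expression CV
    nuclear_fraction_sd: 0.11  # per-cell spread of the localization split
    expected_compartment: both

transport:
  D: 15.0             # um^2/s in-gel diffusivity (band broadening)
  E: 40.0             # V/cm
  t_lysis: 25.0       # s
  t_page: 17.0        # s
  sigma0: 8.0         # um injected band s.d. (~well diameter / 4)

simulation:
  noise_sd: 10.0      # AU additive Gaussian scanner noise per pixel
  migration_cv: 6.4   # % cell-to-cell electromigration variability
  seed: 1

thresholds:
  snr_min: 3.0        # peak calling: SNR > 3
  r2_min: 0.7         # peak calling: R^2 > 0.7

orientation:
  east_is_cytoplasmic: true

timecourse:
  timepoints: [0, 15, 30, 45, 60, 75, 90, 105, 120]  # minutes
  n_cells_per_timepoint: 100
  curve: {peak_time: 60, width: 25, baseline: 0.15, amplitude: 0.45}
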