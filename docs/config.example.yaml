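# Reference configuration for `ligbind run` / ligbind.io.run_pipeline.
# Every key is optional; defaults shown. CLI flags override config values.

seed: 1                      # top-level seed for all simulated randomness
epsilon: 40.0                # ligand:protein concentration ratio for eta
schedule: [0.5, 1, 1.5, 2, 3, 4, 5, 6]   # saturation times (s)

noise:
  intensity_cv: 0.02         # cv of multiplicative noise on measured peaks
  concentration_cv: 0.01     # cv for dialysis concentrations

# Either simulate inputs ...
simulate:
  ligands: ["3-CMC", "4-CMC"]      # shipped templates
  probes:                          # probe -> site (configuration, not chemistry)
    warfarin: site_I
    diazepam: site_II
  dialysis:
    n_replicates: 5
    methods: [ED, UF]

# ... and/or read them from tables (intensity-table / dialysis-table schemas).
inputs:
  intensity_table: null      # CSV path
  dialysis_table: null       # CSV path
  molar_mass_g_per_mol: null # required when dialysis rows use ug/mL

assignment:
  ambiguity_threshold: 10.0    # percentage points between probe medians
  competition_tolerance: 10.0  # median < 100 - this marks a secondary site
  statistic: median            # or mean
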