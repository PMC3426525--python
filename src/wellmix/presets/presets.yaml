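# Frozen scenario presets (versioned so downstream tests are stable).
#
# Descriptor order: cell_count (gamma), prop_S, prop_G2, prop_M,
# prop_apoptotic (beta).  The negative-control-like mixture has three
# population phenotypes whose across-class structure reproduces the
# qualitative association pattern seen in real negative controls:
# wells with more cells sit deeper in G2 and show fewer mitotic
# figures (positive count~G2, negative count~M association), while
# S-phase proportion is roughly flat across classes.  The shared
# within-class copula correlation points the same way.
version: 1
layout:
  n_wells_per_condition: 336
  fields_per_well: 4
  negative_condition: GL2
  positive_condition: KIF11
negative_like:
  pi: [0.50, 0.35, 0.15]
  correlation:
    - [ 1.00, 0.05,  0.30, -0.30, -0.10]
    - [ 0.05, 1.00,  0.10,  0.00,  0.00]
    - [ 0.30, 0.10,  1.00, -0.10,  0.00]
    - [-0.30, 0.00, -0.10,  1.00,  0.10]
    - [-0.10, 0.00,  0.00,  0.10,  1.00]
  classes:
    - name: confluent
      cell_count: [gamma, 40.0, 0.02]     # mean 2000 cells, sd ~316
      prop_S: [beta, 7.0, 28.0]           # mean 0.20
      prop_G2: [beta, 12.0, 28.0]         # mean 0.30
      prop_M: [beta, 1.5, 48.5]           # mean 0.03
      prop_apoptotic: [beta, 2.0, 48.0]   # mean 0.04
    - name: proliferating
      cell_count: [gamma, 30.0, 0.025]    # mean 1200
      prop_S: [beta, 9.0, 31.0]           # mean 0.225
      prop_G2: [beta, 8.0, 32.0]          # mean 0.20
      prop_M: [beta, 3.5, 46.5]           # mean 0.07
      prop_apoptotic: [beta, 2.5, 47.5]   # mean 0.05
    - name: sparse_mitotic
      cell_count: [gamma, 20.0, 0.0333333333] # mean 600
      prop_S: [beta, 8.0, 32.0]           # mean 0.20
      prop_G2: [beta, 5.0, 35.0]          # mean 0.125
      prop_M: [beta, 6.0, 44.0]           # mean 0.12
      prop_apoptotic: [beta, 3.0, 47.0]   # mean 0.06
positive_contrast:
  # Cell-death-inducing positive control: gamma rate x5 (count mean /5)
  # and apoptotic beta mean x5 relative to each negative-like class.
  count_rate_factor: 5.0
  apoptosis_mean_factor: 5.0
with_outliers:
  fraction: 0.05
  outlier_class:
    name: imaging_artifact
    cell_count: [gamma, 6.0, 0.03]        # mean 200, heavily depleted wells
    prop_S: [beta, 2.0, 18.0]             # mean 0.10
    prop_G2: [beta, 2.0, 38.0]            # mean 0.05
    prop_M: [beta, 18.0, 18.0]            # mean 0.50, implausible mitotic pile-up
    prop_apoptotic: [beta, 6.0, 24.0]     # mean 0.20
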