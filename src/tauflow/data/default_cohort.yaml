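# Distribution parameters for the default synthetic two-timepoint cohort:
# a subjective-cognitive-decline (SCD) group and an Alzheimer's disease
# (AD) group, each with three composite tau-staging regions (Braak I/II
# entorhinal, III/IV limbic, V/VI neocortical).
#
# Values are group means (SDs in parentheses in the source cohort) of
# DVR, R1 and their two-year percentage changes from a published
# longitudinal flortaucipir study of 38 SCD subjects and 24 AD patients.
# The pct_change_suvr_* entries are reference values for agreement
# analyses only: SUVr is never sampled, it emerges from the simulated
# kinetics.
schema_version: 1
roi_correlation: 0.7
groups:
  SCD:
    n_subjects: 38
    interval_mean: 2.1
    interval_sd: 0.3
    rois:
      BraakI_II:
        dvr_base_mean: 1.039
        dvr_base_sd: 0.121
        pct_change_dvr_mean: 2.56
        pct_change_dvr_sd: 2.85
        r1_base_mean: 0.708
        r1_base_sd: 0.041
        pct_change_r1_mean: 0.74
        pct_change_r1_sd: 3.96
        pct_change_suvr_mean: 1.85
        pct_change_suvr_sd: 3.27
      BraakIII_IV:
        dvr_base_mean: 1.045
        dvr_base_sd: 0.075
        pct_change_dvr_mean: 2.82
        pct_change_dvr_sd: 2.54
        r1_base_mean: 0.836
        r1_base_sd: 0.036
        pct_change_r1_mean: 0.79
        pct_change_r1_sd: 2.75
        pct_change_suvr_mean: 2.47
        pct_change_suvr_sd: 2.64
      BraakV_VI:
        dvr_base_mean: 1.042
        dvr_base_sd: 0.057
        pct_change_dvr_mean: 2.33
        pct_change_dvr_sd: 2.77
        r1_base_mean: 0.926
        r1_base_sd: 0.043
        pct_change_r1_mean: 0.47
        pct_change_r1_sd: 2.67
        pct_change_suvr_mean: 2.17
        pct_change_suvr_sd: 3.29
  AD:
    n_subjects: 24
    interval_mean: 2.2
    interval_sd: 0.3
    rois:
      BraakI_II:
        dvr_base_mean: 1.277
        dvr_base_sd: 0.146
        pct_change_dvr_mean: 3.48
        pct_change_dvr_sd: 4.16
        r1_base_mean: 0.713
        r1_base_sd: 0.047
        pct_change_r1_mean: -0.87
        pct_change_r1_sd: 5.26
        pct_change_suvr_mean: 3.25
        pct_change_suvr_sd: 5.26
      BraakIII_IV:
        dvr_base_mean: 1.256
        dvr_base_sd: 0.147
        pct_change_dvr_mean: 6.61
        pct_change_dvr_sd: 5.63
        r1_base_mean: 0.835
        r1_base_sd: 0.045
        pct_change_r1_mean: -1.62
        pct_change_r1_sd: 3.71
        pct_change_suvr_mean: 7.52
        pct_change_suvr_sd: 6.66
      BraakV_VI:
        dvr_base_mean: 1.284
        dvr_base_sd: 0.222
        pct_change_dvr_mean: 7.25
        pct_change_dvr_sd: 6.85
        r1_base_mean: 0.904
        r1_base_sd: 0.051
        pct_change_r1_mean: -2.28
        pct_change_r1_sd: 3.67
        pct_change_suvr_mean: 8.21
        pct_change_suvr_sd: 8.03
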