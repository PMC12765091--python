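# Default organ-at-risk QA policies: 17 brain OARs (ESTRO-ACROP consensus set).
#
# All values are documented DEFAULTS intended to be adapted per clinic:
# constraint doses follow common brain planning practice (60 Gy / 30 fx
# prescriptions); dilation/erosion extents are placeholder organ-size-scaled
# probes; colour thresholds are starting points, not clinical reconstructions.
#
# Units: doses Gy, distances mm.  Threshold semantics (see docs/methods.md):
#   dsc_thresholds:            [yellow_below, red_below]
#   hdd_thresholds_mm:         [yellow_above, red_above]
#   dose_margin:               [yellow_within, red_within_or_exceed]  (fractions of constraint)
#   sensitivity_thresholds_gy: [yellow_above, red_above]              (delta dose, Gy)
schema_version: 1
organs:
  brainstem:
    constraint_metric: max
    constraint_dose_gy: 54.0
    dilation_mm: 3.0
    erosion_mm: 2.0
    dsc_thresholds: [0.85, 0.70]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  optic_chiasm:
    constraint_metric: max
    constraint_dose_gy: 54.0
    dilation_mm: 2.0
    erosion_mm: 1.0
    dsc_thresholds: [0.85, 0.70]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  optic_nerve_l:
    constraint_metric: max
    constraint_dose_gy: 54.0
    dilation_mm: 2.0
    erosion_mm: 1.0
    dsc_thresholds: [0.85, 0.70]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  optic_nerve_r:
    constraint_metric: max
    constraint_dose_gy: 54.0
    dilation_mm: 2.0
    erosion_mm: 1.0
    dsc_thresholds: [0.85, 0.70]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  eye_l:
    constraint_metric: max
    constraint_dose_gy: 45.0
    dilation_mm: 3.0
    erosion_mm: 2.0
    dsc_thresholds: [0.85, 0.70]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  eye_r:
    constraint_metric: max
    constraint_dose_gy: 45.0
    dilation_mm: 3.0
    erosion_mm: 2.0
    dsc_thresholds: [0.85, 0.70]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  lens_l:
    constraint_metric: max
    constraint_dose_gy: 10.0
    dilation_mm: 1.5
    erosion_mm: 1.0
    dsc_thresholds: [0.80, 0.60]
    hdd_thresholds_mm: [2.0, 4.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  lens_r:
    constraint_metric: max
    constraint_dose_gy: 10.0
    dilation_mm: 1.5
    erosion_mm: 1.0
    dsc_thresholds: [0.80, 0.60]
    hdd_thresholds_mm: [2.0, 4.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  retina_l:
    constraint_metric: max
    constraint_dose_gy: 45.0
    dilation_mm: 2.0
    erosion_mm: 1.0
    dsc_thresholds: [0.80, 0.60]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  retina_r:
    constraint_metric: max
    constraint_dose_gy: 45.0
    dilation_mm: 2.0
    erosion_mm: 1.0
    dsc_thresholds: [0.80, 0.60]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  cochlea_l:
    constraint_metric: mean
    constraint_dose_gy: 45.0
    dilation_mm: 1.5
    erosion_mm: 1.0
    dsc_thresholds: [0.80, 0.60]
    hdd_thresholds_mm: [2.0, 4.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  cochlea_r:
    constraint_metric: mean
    constraint_dose_gy: 45.0
    dilation_mm: 1.5
    erosion_mm: 1.0
    dsc_thresholds: [0.80, 0.60]
    hdd_thresholds_mm: [2.0, 4.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  pituitary:
    constraint_metric: mean
    constraint_dose_gy: 45.0
    dilation_mm: 1.5
    erosion_mm: 1.0
    dsc_thresholds: [0.80, 0.60]
    hdd_thresholds_mm: [2.0, 4.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  hippocampus_l:
    constraint_metric: mean
    constraint_dose_gy: 30.0
    dilation_mm: 3.0
    erosion_mm: 2.0
    dsc_thresholds: [0.85, 0.70]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  hippocampus_r:
    constraint_metric: mean
    constraint_dose_gy: 30.0
    dilation_mm: 3.0
    erosion_mm: 2.0
    dsc_thresholds: [0.85, 0.70]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  lacrimal_gland_l:
    constraint_metric: mean
    constraint_dose_gy: 25.0
    dilation_mm: 2.0
    erosion_mm: 1.0
    dsc_thresholds: [0.80, 0.60]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
  lacrimal_gland_r:
    constraint_metric: mean
    constraint_dose_gy: 25.0
    dilation_mm: 2.0
    erosion_mm: 1.0
    dsc_thresholds: [0.80, 0.60]
    hdd_thresholds_mm: [3.0, 6.0]
    dose_margin: [0.10, 0.0]
    sensitivity_thresholds_gy: [1.0, 3.0]
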