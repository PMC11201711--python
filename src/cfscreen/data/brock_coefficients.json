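{
  "model": "PanCan (Brock University) nodule malignancy model, full model with spiculation",
  "source": "McWilliams A et al., Probability of cancer in pulmonary nodules detected on first screening CT, N Engl J Med 2013;369:910-919 (supplementary appendix, model 2b)",
  "version": "2013-full-with-spiculation",
  "intercept": -6.7892,
  "age_per_year_centered_62": 0.0287,
  "sex_female": 0.6011,
  "family_history_lc": 0.2961,
  "emphysema": 0.2953,
  "size_coefficient": -5.3854,
  "size_center": 1.58113883,
  "density_part_solid": 0.377,
  "density_non_solid": -0.1276,
  "upper_lobe": 0.6581,
  "nodule_count_per_nodule_centered_4": -0.0824,
  "spiculated": 0.7729
}
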