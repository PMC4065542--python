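# Default model input parameters: point estimate, (low, high) range on the
# natural scale, and the sampling-distribution family used by the PSA.
# Ranges are read as 95% intervals when fitting Beta/Gamma distributions;
# Beta-PERT uses (low, mode=value, high) directly.
#
# Two entries deviate from the primary published table and are documented
# model choices (see docs/methods.md):
#   * hstnt_test_cost: 21.50 (the bottom-up costing figure; the table's 31.5
#     is inconsistent with the reported 4.39-euro unit-cost increment over
#     the 17.11-euro conventional assay). Range is +/-25% of 21.50, the same
#     rule that generated the printed cost ranges.
#   * hfabp_marginal_cost: NOT published anywhere; 10.00 is a placeholder for
#     the marginal cost of adding the H-FABP assay to an hsTnT draw. The
#     combination strategy's per-stage test cost is hstnt_test_cost + this.

ctnt_test_cost:            {value: 17.11, low: 12.8, high: 21.4, family: beta_pert, units: euros}
hstnt_test_cost:           {value: 21.50, low: 16.125, high: 26.875, family: beta_pert, units: euros}
hfabp_marginal_cost:       {value: 10.00, low: 7.5, high: 12.5, family: beta_pert, units: euros}
ami_first_year_cost:       {value: 12446, low: 9334, high: 15557, family: gamma, units: euros}
ami_subsequent_year_cost:  {value: 2092, low: 1569, high: 2615, family: gamma, units: euros}
utility:                   {value: 0.725, low: 0.544, high: 0.906, family: beta, units: utility}
cost_discount_rate:        {value: 0.04, family: fixed, units: rate}
effect_discount_rate:      {value: 0.015, family: fixed, units: rate}
prevalence:                {value: 0.30, low: 0.23, high: 0.38, family: beta_pert, units: probability}
missed_ami_mortality_ratio: {value: 1.9, low: 1.43, high: 2.38, family: beta_pert, units: ratio}
life_expectancy:           {value: 8.3, low: 6.23, high: 10.38, family: beta_pert, units: years}
early_ppci_mortality:      {value: 0.062, low: 0.0468, high: 0.0780, family: beta_pert, units: probability}
delayed_ppci_mortality:    {value: 0.103, low: 0.077, high: 0.1288, family: beta_pert, units: probability}
procedural_mortality:      {value: 0.0072, low: 0.0054, high: 0.009, family: beta_pert, units: probability}

# Diagnostic accuracy (sensitivity/specificity at <=6 h and <=12 h from
# symptom onset), Beta-fitted to the reported 95% confidence intervals.
ctnt_se6:   {value: 0.44, low: 0.32, high: 0.56, family: beta, units: probability}
ctnt_se12:  {value: 0.93, low: 0.85, high: 0.97, family: beta, units: probability}
ctnt_sp6:   {value: 0.92, low: 0.88, high: 0.95, family: beta, units: probability}
ctnt_sp12:  {value: 0.85, low: 0.76, high: 0.91, family: beta, units: probability}
hstnt_se6:  {value: 0.94, low: 0.87, high: 0.98, family: beta, units: probability}
hstnt_se12: {value: 0.95, low: 0.91, high: 0.98, family: beta, units: probability}
hstnt_sp6:  {value: 0.52, low: 0.39, high: 0.65, family: beta, units: probability}
hstnt_sp12: {value: 0.51, low: 0.40, high: 0.62, family: beta, units: probability}
combo_se6:  {value: 0.97, low: 0.90, high: 0.99, family: beta, units: probability}
combo_se12: {value: 0.97, low: 0.93, high: 0.99, family: beta, units: probability}
combo_sp6:  {value: 0.39, low: 0.27, high: 0.51, family: beta, units: probability}
combo_sp12: {value: 0.38, low: 0.27, high: 0.49, family: beta, units: probability}
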