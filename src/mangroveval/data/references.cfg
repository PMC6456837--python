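# Published reference values the scenario run is checked against.
# The stems-removed range is the one implied by the published stand
# tables (the abstract's upper figure of 350 is not derivable from them).
wood_annual_income_idr = 742425000
wood_pppd_usd = 0.933
fishing_pppd_idr = 18048
overfishing_rate_pct = 45.5
peak_age_pre = 25
peak_mai_pre = 5.39
peak_age_post = 25
peak_mai_post = 6.71
mai_gain_pct = 24.5
nrr_max_pct = 11.4
nrr_max_cost_midr = 10
n_income_classes = 6
min_stems_removed = 90
max_stems_removed = 340
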