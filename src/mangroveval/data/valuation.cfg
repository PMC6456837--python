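# Balikpapan Bay direct-use valuation scenario
area_ha = 300
price_idr_per_m3 = 500000
fx = 13300
days_per_year = 365
population = 164
rotation_years = 20
# wood harvest: standing volume per ha at the age-20 harvest
harvest_age = 20
harvest_volume_m3_ha = 98.99
# total annual fishing income of the community, IDR yr-1
fishing_income_idr_yr = 1080353280
# income classing range of the raw household survey, million IDR
income_class_min = 13
income_class_max = 36
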