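# mangroveval

Growth-and-yield analysis and direct-use economic valuation of restored
*Rhizophora apiculata* mangrove stands, built around the study system of
Balikpapan Bay (East Kalimantan, Indonesia): a community whose livelihood
draws on both mangrove timber and the fishery the mangroves sustain.

The package answers three linked questions for forest and coastal-resource
analysts:

1. **How much wood does the stand produce, and when should it be cut?**
   From a stand table (stocking N, mean diameter D, branch-free height H,
   form factor F per measurement age) the standing volume is

   V = N · (π/4) · (D/100)² · H · F   [m³ ha⁻¹]

   and the growth proxies are the mean annual increment MAI = V(t)/t and
   the periodic (current) annual increment PAI = (V(t) − V(t₋₁))/Δt. The
   age at which MAI culminates is the biologically optimal rotation.
2. **What does thinning from below change?** Low thinning removes trees
   more than 2 cm below the stand's mean diameter; contrasting pre- and
   post-thinning stand tables gives stems removed per hectare and the
   relative MAI gain.
3. **How do wood and fishing incomes compare?** Household incomes are
   grouped into Sturges classes (≈ 1 + 3.332·log₁₀N classes), fishing
   operations are characterised by their monthly nominal rate of return
   i = (Iₙ/V₀)^(1/n) − 1, and both income streams are converted to income
   per person per day; the relative excess of fishing over wood income is
   reported as the overfishing rate.

A synthetic-data module generates stand trajectories (Chapman–Richards
diameter/height curves, exponential survival, linearly declining form
factor), tree lists and household surveys with the statistical shape of
the study data, so the whole pipeline is testable without field records.

## Worked example

The published pre-thinning stand table ships with the package. Computing
its growth columns:

```
$ mangroveval grow --input stand.csv --output growth.csv --round 2
peak MAI 5.39 m3/ha/yr at age 25
$ head -4 growth.csv
age,n,d_cm,h_m,f,tv,mai,pai
3,2500,5.0,2.0,0.85,8.34,2.78,
7,1750,7.2,4.0,0.82,23.37,3.34,3.76
10,1700,8.4,5.0,0.8,37.68,3.77,4.77
```

The age-3 stand of 2500 stems (D = 5 cm, H = 2 m, F = 0.85) carries
8.34 m³ ha⁻¹; mean annual increment climbs from 2.78 m³ ha⁻¹ yr⁻¹ to a
culmination of 5.39 at age 25 — the optimal rotation age. Reproducing the
whole study scenario:

```
$ mangroveval reproduce
peak_age_pre                 computed=            25 reference=          25 rel_err=0.00e+00 ok
peak_mai_pre                 computed=       5.38838 reference=        5.39 rel_err=3.00e-04 ok
peak_mai_post                computed=       6.71419 reference=        6.71 rel_err=6.24e-04 ok
mai_gain_pct                 computed=       24.6064 reference=        24.5 rel_err=4.34e-03 ok
wood_annual_income_idr       computed=   7.42425e+08 reference= 7.42425e+08 rel_err=0.00e+00 ok
wood_pppd_usd                computed=      0.932533 reference=       0.933 rel_err=5.00e-04 ok
fishing_pppd_idr             computed=         18048 reference=       18048 rel_err=0.00e+00 ok
overfishing_rate_pct         computed=       45.5168 reference=        45.5 rel_err=3.70e-04 ok
nrr_max_pct                  computed=        11.393 reference=        11.4 rel_err=6.18e-04 ok
...
```

Thinning raises the culmination MAI from 5.39 to 6.71 m³ ha⁻¹ yr⁻¹
(a ~24.5% gain) while removing 90–340 stems ha⁻¹. Harvesting the 300 ha
at the age-20 standing volume of 98.99 m³ ha⁻¹ at IDR 500,000 per m³ over
a 20-year rotation yields IDR 742,425,000 per year — US$ 0.933 per person
per day across the 164-person community — versus IDR 18,048 per person
per day from fishing, an income gap that puts the overfishing rate at
45.5%. The most cost-efficient fishing operation (11.4% monthly nominal
rate of return) runs at an operating cost of IDR 10 million per year.

Other subcommands: `thin` (low-thin a tree list), `thin-contrast`
(pre/post stand comparison), `value` (income classing and valuation from
a household CSV plus a key–value config), `simulate stand|households`
(synthetic inputs).

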