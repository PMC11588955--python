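# Base-case model inputs, per-protocol survival population.
# Flat key-value schema; see embocea.parameters for units and meaning.
schema_version: 1
population: pp

# Survival medians (months)
median_os_tare: 30.2
median_os_deb: 15.6
median_pfs_tare: 12.83
median_pfs_deb: 9.10
median_os_systemic: 19.2

# Annual clinical rates (fractions per year)
annual_decomp_tae_eligible: 0.118
annual_decomp_systemic: 0.534
annual_survival_decomp: 0.25

# Costs (JPY)
deb_admission: 845320
microsphere_price: 1440000
tare_admission_other: 734896
outpatient_monthly: 98455
systemic_monthly: 1242800
decomp_monthly: 247690
pre_angio: 36000
scinti: 22215
ct_followup: 30000

# Utilities (QALY weights)
u_local: 0.788
u_eligible: 0.768
u_refractory: 0.748
u_decomp: 0.524
u_dead: 0.0

# Cycle structure and decision settings
cycle_months: 2
total_cycles: 30
discount_annual: 0.02
wtp: 5000000
max_sessions_deb: 6
max_sessions_tare: 2
jpy_per_usd: 160
jpy_per_gbp: 180

# Engine toggles (calibrated defaults; see docs/methods.md)
half_cycle_correction: false
session_policy: per_cycle_while_eligible
outpatient_in_treatment_cycles: true
ct_schedule: treatment
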