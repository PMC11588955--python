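# embocea

Markov cohort cost-effectiveness model comparing **transarterial
radioembolization (TARE)** with **drug-eluting-bead chemoembolization
(DEB-TACE)** for unresectable hepatocellular carcinoma, from the
perspective of the Japanese healthcare payer.

TARE delivers yttrium-90-loaded microspheres intra-arterially and
prolongs progression-free survival relative to chemoembolization, but
the microspheres are expensive (8,000 GBP per session in the UK). The
question the model answers: at what reimbursement price is TARE
cost-effective against DEB-TACE under the Japanese willingness-to-pay
threshold of 5 million JPY per quality-adjusted life year (QALY)?

The package is aimed at health-economics analysts: it exposes the full
pipeline as a library plus a small CLI — parameter handling, synthetic
claims-data cost construction, transition-probability derivation, the
cohort engine, and deterministic/probabilistic sensitivity analyses.

## The model

A five-state Markov cohort model run over thirty 2-month cycles
(5 years): **local** (tumour controlled), **TAE-eligible progressive**
(progressed, still a candidate for embolization), **TAE-refractory
progressive** (systemic therapy with atezolizumab + bevacizumab),
**decompensated cirrhosis** (palliative care), and **death**.

Per-cycle transition probabilities come from median time-to-event data
under a constant-hazard approximation,

```
p = 1 − 0.5^(cycle / median),
```

annual rates are rescaled as `p = 1 − (1 − annual)^(cycle/12)`, and the
exits from the treatable states form a competing-risk cascade (death,
then decompensation among survivors, then progression among the rest):

```
P4 = p_death
P3 = (1 − P4) · p_decomp
P2 = (1 − P4)(1 − p_decomp) · p_prog,   p_prog = 1 − e^(−(ln2/mPFS − ln2/mOS)·cycle)
P1 = 1 − P2 − P3 − P4
```

Costs (JPY) and utilities accrue per cycle and are discounted at 2%
per year. Embolization sessions are capped at 2 (TARE) and 6
(DEB-TACE); the incremental cost-effectiveness ratio is
`ICER = ΔC / ΔE` against a 5 M JPY/QALY threshold. Sensitivity
analyses: one-way deterministic (tornado + threshold search by Brent's
method) and probabilistic (gamma draws for costs and survival medians,
beta for utilities and annual rates, triangular for the discount rate;
acceptability curves from 10,000 Monte-Carlo iterations).

The DEB-TACE admission cost itself is built from inpatient claims
records: admissions claiming selective TACE (code K615_2) for
hepatocellular carcinoma (ICD-10 C220) with drug-eluting beads and no
lipiodol are stratified by severe hepatobiliary complications, and the
prevalence-weighted mean becomes the per-admission cost. A synthetic
claims generator reproduces that cohort structure for end-to-end
testing (`embocea.claims`).

## Worked example

```python
from embocea import load_parameters, run_cohort, compare, threshold_search

params = load_parameters()            # intention-to-treat defaults
tare = run_cohort("tare", params)
deb = run_cohort("deb", params)
c = compare(tare, deb, wtp=5_000_000)
print(f"TARE : {tare.total_cost:>12,.0f} JPY  {tare.total_qaly:.2f} QALY")
print(f"DEB  : {deb.total_cost:>12,.0f} JPY  {deb.total_qaly:.2f} QALY")
print(f"ICER : {c.icer:,.0f} JPY/QALY  (cost-effective: {c.cost_effective})")
print(f"price threshold: {threshold_search('microsphere_price', params):,.0f} JPY")
```

prints

```
TARE :    9,853,942 JPY  1.68 QALY
DEB  :    7,499,735 JPY  1.22 QALY
ICER : 5,173,591 JPY/QALY  (cost-effective: False)
price threshold: 1,399,120 JPY
```

i.e. over five years TARE costs 2.35 M JPY more and yields 0.46 more
QALYs than DEB-TACE; at 5.17 M JPY per QALY gained it narrowly exceeds
the Japanese threshold, and lowering the microsphere reimbursement
price from 1.44 M to below about 1.40 M JPY (≈ 2.8%) would make TARE
cost-effective. The same analyses run from the shell:

```
embocea run  --population itt --out out/run     # traces + comparison JSON
embocea dsa  --out out/dsa                      # tornado CSV + thresholds
embocea psa  --n 10000 --seed 1 --out out/psa   # scatter + CEAC CSV
embocea synth --n 6986 --seed 1 --out out/synth # synthetic claims cohort
```

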