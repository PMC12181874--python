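# faersig

Disproportionality signal detection and time-to-onset analysis for
FAERS-style spontaneous adverse-event reports.

Spontaneous reporting databases (the FDA Adverse Event Reporting System and
its quarterly ASCII extracts) have no exposure denominator, so post-market
drug-safety screening works by *disproportionality*: for a target drug and
each adverse-event preferred term (PT), build the 2×2 table

|              | target PT | other PTs |
|--------------|-----------|-----------|
| target drug  | a         | b         |
| other drugs  | c         | d         |

and flag the PT when four statistics jointly clear their screening
thresholds:

- **ROR** = ad/(bc), CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` — flag when
  the lower bound exceeds 1 and a ≥ 3;
- **PRR** = [a/(a+b)]/[c/(c+d)] with Pearson χ² — flag when PRR ≥ 2, χ² ≥ 4
  and a ≥ 3;
- **IC** (BCPNN information component) = log₂[a·n/((a+c)(a+b))] — flag when
  IC025 > 0;
- **EBGM** (crude observed/expected ratio, = 2^IC) — flag when EBGM05 > 2.

`faersig` implements the whole workflow: parsing the dollar-delimited
quarterly tables (DEMO/DRUG/REAC/OUTC/THER/INDI) with partial-date
handling, FDA-rule deduplication (per CASEID keep the latest FDA_DT, ties
to the largest PRIMARYID), primary-suspect keyword selection of the target
drug, the four-algorithm screen, characteristics and system-organ-class
tables, time-to-onset binning, a maximum-likelihood Weibull
shape-parameter (WSP) analysis that classifies the hazard of onset as
decreasing/constant/increasing, and subgroup-stratified reruns. A
synthetic-data generator with planted signals and a ground-truth manifest
makes everything testable without the multi-gigabyte FAERS download.
It was built around pegvaliase (Palynziq), the enzyme-substitution therapy
for phenylketonuria, as the worked target drug; every drug-specific input
(name keywords, date window, PT→SOC map) is configuration.

## Worked example

Generate a synthetic corpus (5,000 cases, ~10% naming the target drug as
primary suspect, relative risks 2/5/10 planted on three PTs), run the
pipeline, and fit the onset model:

```python
from faersig import (SyntheticConfig, generate, deduplicate, build_caseset,
                     detect_signals, compute_onsets, weibull_fit)
from faersig.preprocess import background_pt_sets
from faersig.io import read_meddra_map

ds = generate(SyntheticConfig(n_cases=5000, seed=1), outdir="demo")
deduped = deduplicate(ds.demo)
caseset = build_caseset(deduped, ds.drug, ds.reac, ds.outc, ds.ther,
                        patterns=["pegvaliase", "palynziq"],
                        window=("2018-07-01", "2023-06-30"))
background = background_pt_sets(deduped, ds.reac, caseset.primaryids)
results = detect_signals(caseset, background,
                         meddra_map=read_meddra_map("demo/meddra_map.csv"))
print(results.summary())
print(weibull_fit(compute_onsets(caseset)[0]).summary())
```

prints

```
Disproportionality screen (ROR / PRR / BCPNN-IC / EBGM)
  target reports:     489
  background reports: 4511
  distinct PTs:       100
  joint signals:      2

  top signals by case count:
    Event Term 0041                  a=   62  ROR 10.59 (7.34-15.29)  chi2 235.9  IC025 2.14  EBGM05 3.57
    Event Term 0031                  a=   41  ROR 4.08 (2.80-5.94)  chi2 62.1  IC025 1.22  EBGM05 2.05

Weibull shape-parameter (WSP) analysis of time to onset
  n used:  226
  shape beta:  0.587  (95% CI 0.531-0.648)
  scale alpha: 24.0 days  (95% CI 19.0-30.4)
  log-likelihood: -977.74
  hazard classification: early failure
```

Reading this: the PTs planted at relative risks 10 and 5 are recovered as
joint signals with RORs near their planted values (`a` is the case count
for the drug–PT pair); the PT planted at relative risk 2 is *not* jointly
flagged — the EBGM05 > 2 and PRR ≥ 2 rules sit exactly at that effect
size, so the joint screen is deliberately conservative there (see
`docs/methods.md`). The Weibull shape β̂ ≈ 0.59 (CI below 1) recovers the
generator's β = 0.6 and classifies onsets as "early failure": the hazard
of the adverse event falls with time on drug, i.e. events cluster shortly
after treatment start.

The same pipeline runs from the shell:

```sh
faersig synth --outdir demo --seed 1 --n-cases 5000
faersig analyze --config run.yaml     # input_dir, output_dir, patterns, map
```

writing `signals.csv`, `soc_table.csv`, `characteristics.csv`,
`onsets.csv`, `onset_bins.csv`, `weibull.csv`, `subgroup_*.csv`, a
provenance log of per-stage report counts, and the resolved configuration.

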