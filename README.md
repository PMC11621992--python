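# rfjem

Occupational RF-EMF exposure assessment and brain-tumor case-control
analysis with a job-exposure matrix (JEM).

Occupational epidemiologists studying radiofrequency electromagnetic
fields (RF-EMF, 100 kHz–300 GHz) rarely have personal dosimetry for study
participants.  A JEM substitutes: a lookup table assigning each 4-digit
ISCO88 occupation code an exposure *intensity* — the time-weighted-average
ICNIRP squared ratio `(Ḡ(f)/G_RL(f))²`, the squared mean field level over
its frequency-specific occupational reference level, proportional to SAR
above 100 kHz — and a *prevalence* of exposure, separately for electric
(E) and magnetic (H) fields.  `rfjem` links such a matrix to lifetime job
histories in a stratified case-control study (glioma and meningioma vs
population controls, matched on 5-year age band, sex and country/region)
and estimates exposure-response odds ratios.

The pipeline:

1. **Linkage** under three increasingly specific methods — M1: all
   exposed occupations; M2: only occupations with exposure prevalence at
   or above the median among exposed occupations; M3: only jobs with
   participant-reported RF-EMF source use.
2. **Metrics** — per-year intensity series (concurrent jobs averaged),
   summed into cumulative exposure for lags of 1/5/10 (optionally
   15/20/25) years and windows 1–4/5–9 (optionally 10–14/15–19/20–24)
   years before the reference date (diagnosis for cases, interview minus
   the cases' median diagnosis-interview gap for controls); time-weighted
   averages divide by years worked in the same span.
3. **Categories** — never-exposed as reference, then four levels cut at
   the 50th/75th/90th percentiles of the exposed-control distribution.
4. **Estimation** — exact conditional logistic regression, stratified on
   the matching factors and adjusted for education.  The per-stratum
   likelihood

       log [ exp(Σ_cases η) / Σ_{|S|=d} exp(Σ_{i∈S} η_i) ]

   is evaluated with the elementary-symmetric-function recursion
   `f(j,r) = f(j−1,r) + f(j−1,r−1)·e^{η_j}`; odds ratios are `exp(β)` with
   Wald 95% CIs, plus an ordinal trend test per cell.

A first-class synthetic-data module generates matrices, job histories and
outcomes with known effect sizes (the real study data are not publicly
deposited), so every stage is testable end to end, including parameter
recovery and trend-test calibration.

## Worked example

```python
import numpy as np
from rfjem import fit_clogit, odds_ratios, trend_test

rng = np.random.default_rng(0)
n = 1500
strata = rng.integers(0, 60, n)                  # matching-factor strata
category = rng.integers(0, 5, n)                 # exposure category 0..4
eta = np.where(category == 4, 0.4, 0.0) + 0.3 * rng.standard_normal(60)[strata]
y = rng.random(n) < 1.0 / (1.0 + np.exp(-(eta - 0.5)))

X = np.column_stack([(category == k).astype(float) for k in (1, 2, 3, 4)])
fit = fit_clogit(X, y, strata, names=[f"cat{k}" for k in (1, 2, 3, 4)])
print(odds_ratios(fit).round(3).to_string(index=False))
```

prints

```
term    OR  CI_low  CI_high
cat1 1.107   0.787    1.556
cat2 1.251   0.888    1.763
cat3 1.087   0.773    1.529
cat4 1.369   0.986    1.901
```

— the top category recovers the simulated effect (true OR `exp(0.4) ≈ 1.49`
is inside its interval) while the null categories sit near 1.  The
`examples/` directory walks through each capability the same way: building
a matrix from source measurements, exposure metrics for a single career
(including the exact identity `lag1 = win1_4 + win5_9 + lag10`), the
conditional-logistic fitter, and the full synthesize-then-analyse
pipeline (`python examples/04_full_pipeline.py`).

There is also a thin CLI:

```sh
rfjem synth --seed 1 --out study/           # jem.csv, participants.csv, jobs.csv, truth.json
rfjem validate --jem study/jem.csv
rfjem run --config cfg.yaml                 # results.csv, cutpoints.csv, ledger.csv, run.log
```

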