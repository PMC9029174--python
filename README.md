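# pippk

Population pharmacokinetics of piperacillin in critically ill adults:
structural two-compartment modelling with a renal-function covariate,
nonparametric population estimation, Bayesian individual posteriors,
internal/external model evaluation, and Monte Carlo dosing simulation
(PTA/FTA) — together with a synthetic-cohort generator that emulates the
study designs so the whole pipeline runs and is testable without patient
data.

It is written for pharmacometricians and infectious-disease researchers
who want a reproducible, scriptable implementation of this analysis
chain: the kind of workflow usually run inside Pmetrics/NONMEM, exposed
here as an importable Python library.

## The model

Piperacillin disposition follows a linear two-compartment model with
zero-order infusion input and first-order elimination:

    dA1/dt = R(t) − (ke + KCP)·A1 + KPC·A2,   ke = CL/V
    dA2/dt = KCP·A1 − KPC·A2,                 C = A1/V

Clearance carries a renal covariate link, **CL = TVCL · (CRCL/60)**,
with CRCL the body-surface-area-normalised creatinine clearance
(mL/min/1.73 m²) and TVCL the typical clearance at the CRCL = 60
reference. Residual error is Gaussian with SD = γ·(1 + 0.1·C), γ = 5.

The population model is nonparametric: a discrete distribution of
support points over (TVCL, V, KCP, KPC) fitted by adaptive-grid maximum
likelihood (EM mixing weights — provably monotone — plus pattern-search
grid refinement and a simplex polish). Individual (Bayesian posterior)
and population predictions feed goodness-of-fit, VPC, NPDE and
Bland–Altman diagnostics, and external validation by mean prediction
error (bias) and root-mean-square prediction error (precision) with 95%
CIs and a 20% relative-bias acceptance rule.

Dosing simulations sample the population (fitted distribution or
log-normals matched to the published moments), simulate a steady-state
interval per virtual patient, and score the fT>MIC pharmacodynamic
index with 30% protein binding (fu = 0.70): PTA across an MIC grid and
FTA against an isolate-frequency MIC distribution truncated at the
clinical breakpoint (16 mg/L for *P. aeruginosa*; FTA ≥ 85% is
"optimal").

See `docs/methods.md` for assumptions, numerical choices and
limitations.

## Worked example

`examples/dosing_simulation.py` samples 1000 virtual patients from the
published population moments and scores two empiric regimens:

```text
PTA for 4 g q6h (0.5-h infusion), CrCL 60, 50% fT>MIC target:
  MIC  0.0625 mg/L  PTA 100.0%
  ...
  MIC 16.0000 mg/L  PTA  99.9%
  MIC 32.0000 mg/L  PTA  99.6%
  MIC 64.0000 mg/L  PTA  93.5%

FTA (%) against the synthetic MIC distribution:
regimen     target   CrCL30  CrCL60  CrCL90  CrCL130
4 g q6h    50%      100.0   100.0    99.9    99.7
4 g q6h   100%      100.0   100.0    99.9    99.4
4 g q8h    50%      100.0   100.0    99.9    99.1
4 g q8h   100%      100.0   100.0    99.8    98.4
```

PTA and FTA fall as renal function rises (the covariate link scales
clearance with CRCL, so high-clearance patients clear the drug sooner),
q6h dominates q8h at equal dose, and the stricter 100% fT>MIC target is
never easier than the 50% target. The absolute percentages sit high
because the deep peripheral compartment of the reference parameters
(KCP/KPC ≈ 14) accumulates drug strongly at steady state; the *ordering
pattern* is the scientifically validated output, and the synthetic MIC
distribution is a stand-in for a live surveillance table.
The other examples cover cohort simulation (`simulate_cohort.py`),
population fitting with truth comparison (`fit_population.py`), the
diagnostic panel (`diagnostics_checks.py`) and external validation
(`external_validation.py`); each prints a few annotated numbers and
finishes in seconds to a couple of minutes.

A config-driven end-to-end run (fit → posteriors → diagnostics →
validation → dosing) is available as
`pippk.run_pipeline(PipelineConfig(...), outdir)`, producing
`fit.json`, `predictions.csv`, `diagnostics/`, `validation.json`,
`pta.csv`/`fta.csv` and a seed-stamped `log.txt`.

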