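# troponin-cea

A decision-analytic cost-effectiveness model for biomarker-based diagnosis of
acute myocardial infarction (AMI) in patients presenting to hospital with
chest pain, built for health-economic analysts who want a tested, fully
reproducible implementation of the classic two-stage troponin testing tree.

Three diagnostic strategies are compared from a Dutch health-care
perspective over a lifetime horizon:

1. **cTnT** — conventional (4th-generation) cardiac troponin T at ≤6 h from
   symptom onset, repeated at ≤12 h if negative;
2. **hsTnT** — the high-sensitive (5th-generation) assay, same schedule;
3. **hsTnT + H-FABP** — hsTnT combined with heart-type fatty acid-binding
   protein, same schedule.

## The model

Patients carry AMI with prevalence *p* = 0.30. Bayesian revision of the
two-stage test cascade (stage-wise sensitivity Se₆, Se₁₂ and specificity
Sp₆, Sp₁₂, conditionally independent given disease status) yields six
terminal pathways with joint probabilities

```
P(TP_early) = p·Se₆              P(FP_early) = (1−p)·(1−Sp₆)
P(TP_late)  = p·(1−Se₆)·Se₁₂     P(FP_late)  = (1−p)·Sp₆·(1−Sp₁₂)
P(FN_miss)  = p·(1−Se₆)·(1−Se₁₂) P(TN)       = (1−p)·Sp₆·Sp₁₂
```

Detected AMI receives primary PCI; early detection carries in-hospital
mortality 0.062, delayed detection 0.103, each combined with procedural
mortality 0.0072 as independent risks. Missed AMI dies at 1.9 × the early
baseline. Survivors live 8.3 years (discounted at 1.5%/year), weighted by a
post-AMI utility of 0.725 to give QALYs; AMI treatment costs €12,446 in the
first year and €2,092 per subsequent year (discounted at 4%/year). Strategies
are compared by incremental cost-effectiveness ratios (ICER = ΔC/ΔE on
unrounded increments), and uncertainty is handled by one-way sensitivity
analysis over every parameter's range and by probabilistic sensitivity
analysis (Beta / Beta-PERT / Gamma distributions, net-monetary-benefit
acceptability curves). A patient-level microsimulation sharing the tree's
accrual code serves as an independent oracle for the analytic expectations.

## Worked example

```python
>>> from troponin_cea import default_parameters, evaluate_all, incremental_analysis
>>> results = evaluate_all(default_parameters())
>>> for r in results:
...     print(f"{r.name:13s} cost €{r.expected_cost:8.2f}  LY {r.expected_ly:.4f}  "
...           f"QALY {r.expected_qaly:.4f}  AMI survival {r.ami_survival:.4f}")
cTnT          cost € 7310.54  LY 2.1426  QALY 1.5534  AMI survival 0.9081
hsTnT         cost € 7389.90  LY 2.1913  QALY 1.5887  AMI survival 0.9288
hsTnT+H-FABP  cost € 7405.40  LY 2.1942  QALY 1.5908  AMI survival 0.9300
>>> incremental_analysis(results, "qaly").to_frame()[["comparison", "delta_cost", "delta_qaly", "icer"]]
              comparison  delta_cost  delta_qaly         icer
0          hsTnT vs cTnT   79.353905    0.035330  2246.076546
1   hsTnT+H-FABP vs cTnT   94.860214    0.037449  2533.065360
2  hsTnT+H-FABP vs hsTnT   15.506309    0.002119  7318.531481
```

Read: switching from the conventional to the high-sensitive assay raises a
chest-pain patient's AMI hospital-survival probability by 2.1 percentage
points, worth 0.035 discounted QALYs, for €79.35 of lifetime cost — about
€2,246 per QALY, far below the €20,000 Dutch willingness-to-pay threshold.
Adding H-FABP buys a further 0.0021 QALYs at ≈€7,300 per QALY.

The same numbers, plus the PSA, tornado and microsim-validation tables, come
from the numbered drivers (each writes CSVs under `results/`):

```sh
python analysis/01_basecase.py
python analysis/02_psa.py
python analysis/03_owsa.py
python analysis/04_validate_microsim.py
```

or from the CLI: `troponin-cea basecase|psa|owsa|simulate --outdir DIR`
(see `troponin-cea --help`; parameters live in a YAML config, defaulting to
the shipped `src/troponin_cea/data/params_table1.yaml`).

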