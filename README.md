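# olfrisk

Probabilistic occupational-risk assessment for dynamic-olfactometry
panelists.

## The problem

Dynamic olfactometry (EN 13725) measures the odor concentration of
industrial emission samples by presenting them, progressively less
diluted, to a panel of human assessors. The samples cannot be filtered
or pre-treated, so panelists inhale whatever chemicals the emission
contains — briefly, intermittently, and at widely varying
concentrations. That exposure pattern fits none of the usual
occupational-hygiene machinery, and a deterministic risk estimate from
any single sample set generalizes poorly across the enormous
variability of samples, categories and panelist workloads.

`olfrisk` implements a probabilistic alternative: every exposure input
is treated as a random variable fitted from an annual laboratory
survey, and the risk metrics are obtained as Monte Carlo distributions
whose 95th percentiles are compared with acceptability thresholds.

## The model

For compound *i* in a sample with odor concentration C_od (ou_E/m³),
the inhaled (exposure) concentration is

    Cin_i = (C_i / C_od) · k,        k = ΔZ_max · 2 = 10

where C_i is the chemical concentration in the undiluted sample and the
safety factor k combines the maximum admissible panel deviation
(ΔZ_max = 5 from retrospective screening) with the confirmation
presentation at twice the perception concentration.

Non-carcinogenic risk is the hazard index, carcinogenic risk the
inhalation risk:

    HI = Σ_i Cin_i / OEL_i
    IR = Σ_i Cin_i · IUR_i · (N_Y · F_S · N_PR · N_R · IT) / (AT · LT)

with OEL_i the occupational exposure limit (short-term 15-min where
available, 8-h TWA as a conservative fallback), IUR_i the inhalation
unit risk, N_Y working years, F_S samples/year, N_PR presentations per
sample, N_R = 3 rounds, IT = 3 s inhalation time per presentation,
AT = 365 d/yr and LT = 70 yr.

Each randomized input (per-compound Cin_i; N_PR, F_S, N_Y) follows a
truncated Gaussian whose μ, σ, MIN, MAX are the sample mean, standard
deviation and extremes of the observed data. Per category, the Monte
Carlo engine (default 1000 iterations) draws all inputs independently
within each iteration and sums within the iteration. A category is
acceptable when the 95th percentile of HI stays strictly below 1 and of
IR strictly below 1e-5. Categories without any IUR-bearing compound
report IR as explicitly "not computable". A replicate sensitivity test
(5 independent-seed reruns, pairwise Kolmogorov–Smirnov CDF distances)
checks that the iteration count makes the result run-independent.

Because real survey data of this kind are confidential, the package
ships a synthetic-data generator producing laboratory years with the
same structure: per-category compound panels with right-skewed
(log-normal) concentrations, log-normal odor concentrations, a
partial-characterization design (25% of samples carry chemistry), and
a dispersed panelist survey.

## Worked example

```python
from olfrisk import default_scenario, generate_dataset, IRNotComputable
from olfrisk.synthetic import default_tox_table
from olfrisk.pipeline import fit_all, run_assessment

dataset = generate_dataset(default_scenario(master_seed=1))
fitted = fit_all(dataset.samples, dataset.survey, default_tox_table())
result = run_assessment(fitted, iterations=1000, seed=1)

for name, hi in result.hi.items():
    ir = result.ir[name]
    ir_txt = (f"IR p95 = {ir.summary.p95:.2e}"
              if not isinstance(ir, IRNotComputable) else "IR not computable")
    print(f"{name:24s} HI p95 = {hi.summary.p95:.2e} "
          f"({'ok' if hi.verdict else 'FLAG'})  {ir_txt}")
```

prints

```
biofuel                  HI p95 = 5.77e-02 (ok)  IR not computable
biomass                  HI p95 = 2.17e-01 (ok)  IR p95 = 5.95e-08
bitumen                  HI p95 = 3.06e-02 (ok)  IR p95 = 5.73e-08
hydrocarbon_tanks        HI p95 = 2.37e-02 (ok)  IR p95 = 6.42e-08
petrochemical_cracking   HI p95 = 7.09e-02 (ok)  IR p95 = 2.64e-07
refinery                 HI p95 = 6.29e-02 (ok)  IR p95 = 1.23e-07
wwtp                     HI p95 = 2.65e-01 (ok)  IR not computable
```

Every category's HI 95th percentile sits well below 1 and every
computable IR 95th percentile is at least two orders of magnitude below
1e-5, so the synthetic laboratory year poses negligible non-carcinogenic
and carcinogenic risk to the panel; the two categories without
carcinogenic compounds (wwtp, biofuel) are reported as such rather than
as zero risk.

The same pipeline is available from the shell:

```sh
olfrisk simulate --config config.yaml --out-dir out   # synthetic CSVs
olfrisk fit --config config.yaml --out-dir out        # fitted specs + exclusions
olfrisk run --config config.yaml --out-dir out        # results.csv, CDF/PDF series
olfrisk sensitivity --config config.yaml --out-dir out
```

where `config.yaml` can be as small as `scenario: default`. `run` exits
with status 1 when any category is flagged unacceptable, and reruns
with the same config and seed are byte-identical.

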