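# Methods

## Scope and model

`olfrisk` estimates the occupational chemical risk incurred by the
human assessors (panelists) of a dynamic-olfactometry laboratory. The
core quantities are the hazard index HI (non-carcinogenic) and the
inhalation risk IR (carcinogenic), evaluated not as point values but as
Monte Carlo distributions that propagate the variability of the
laboratory's annual workload.

The exposure concentration of compound *i* during an analysis is

    Cin_i = (C_i / C_od) · k

C_i is the compound's concentration in the undiluted sample (µg/m³
canonically; mg/m³ accepted at ingest and converted exactly once),
C_od the sample's odor concentration (ou_E/m³), and k a conservative
safety factor. k = ΔZ_max · 2 = 10 by default: retrospective screening
allows an individual threshold estimate to deviate from the panel
geometric mean by a factor ΔZ_max = 5, and the confirmation
presentation doubles the perceived concentration. Cin_i is therefore a
worst-case inhaled concentration, not an average one.

Risk metrics:

    HI = Σ_i Cin_i / OEL_i
    IR = Σ_i Cin_i · IUR_i · f,   f = (N_Y · F_S · N_PR · N_R · IT) / (AT · LT)

HI deliberately involves no exposure-duration terms: it compares a
momentary inhaled concentration against a limit concentration. IR
scales the concentration-risk product by the dimensionless lifetime
exposure fraction f; IT is in seconds and is divided by 86 400 s/day so
that the ratio against AT·LT (days) is dimensionless — the only
dimensionally consistent reading with AT = 365 d/yr and LT = 70 yr.

### Conservative assumptions (structural, not tunable)

* k = 10 applied to every measurement, although the maximal panel
  deviation is rare in practice.
* All N_PR presentations are charged at the full confirmatory
  concentration; the true earlier presentations are diluted by the
  olfactometer's 2^-n ladder. The test suite verifies that a
  ladder-discounted reference is always strictly smaller for N_PR > 1.
* An 8-h TWA OEL substitutes for a missing short-term OEL even though
  panelist exposure is far shorter than 40 h/week; 8-h values are lower,
  so the hazard quotient is overestimated.
* Exposure parameters are laboratory-global and are applied to each
  category as if the panel's entire workload belonged to that category.

## Randomization

Every randomized input — Cin_i per (category, compound); N_PR, F_S,
N_Y globally — follows a truncated Gaussian with parameters
(μ, σ, MIN, MAX) equal to the sample mean, sample standard deviation
(n−1 denominator; σ = 0 for a single observation) and observed extremes
of the data. μ and σ parameterize the *parent* normal, which is then
truncated; the realized mean of the truncated law therefore differs
from μ under asymmetric truncation. This literal convention was chosen
over moment-matching the truncated law; the closed-form helpers
(`truncated_normal_ppf`, `truncated_normal_moments`) and all tests use
the same convention, so the discrepancy is expected and accounted for.

Per-compound concentration specs are fitted on detected values only.
Treating a compound's absence from a characterized sample as a zero
would force MIN = 0 for every compound and distort every fit; absence
is absence. Detection counts per (category, compound) are logged.

Sampling is inverse-CDF on the truncated interval: u uniform on
[Φ(α), Φ(β)], draw = μ + σ·Φ⁻¹(u). This has no rejection loop (narrow
windows cost nothing) and is exactly affine-equivariant, which makes
"doubling k doubles every draw" hold bitwise at fixed seed — a property
the test suite asserts exactly.

N_PR is a count: continuous draws are rounded half-to-even and clamped
to [max(ceil(MIN), 1), floor(MAX)]. A continuous variant is available
(`simulate_ir(..., integer_n_pr=False)`); integer rounding is the
default.

Seeding: a single master seed; each parameter, compound and replicate
consumes an independent child stream derived from SHA-256 hashes of a
name path fed to `numpy.random.SeedSequence`. Adding a compound or
running IR after HI never perturbs another stream's draws. Derived
integer seeds are kept below 2^31.

## Simulation and acceptability

Default 1000 iterations per category (configurable). Within an
iteration all inputs are drawn independently: no inter-compound
correlation is modelled — a known simplification; emission chemistry
can be correlated across compounds from the same process, which
independent draws ignore.

Summaries report mean, sd, and the 25th/50th/75th/95th percentiles plus
the maximum, using linear interpolation between order statistics (the
numpy default; the convention is recorded in output metadata). A
category is acceptable when the 95th percentile (configurable) is
*strictly* below the threshold: HI < 1, IR < 1e-5. Equality is
unacceptable. Categories whose detected compounds all lack an IUR get
an explicit `IRNotComputable` marker instead of a distribution; this is
a scientific statement (no carcinogen identified), not a zero.

## Sensitivity test

`run_replicates` reruns the simulation `replicate_count` (default 5)
times with sequential child seeds and computes all pairwise two-sample
Kolmogorov–Smirnov sup distances between the draw sets. The stability
verdict uses a default tolerance of 0.05 at 1000 iterations — under the
KS null for n = m = 1000 the 95% critical distance is ≈ 0.061, so
same-distribution replicates pass with high probability while a genuine
distributional shift of a few percent of probability mass fails. The
tolerance is a declared convention (the underlying criterion is visual
CDF overlap) and is configurable.

## Synthetic data generator

The generator emulates the structure of a confidential annual
laboratory survey, with known ground truth:

* **Categories.** Each has n_samples odor-measured samples of which
  exactly round(chem_fraction · n_samples) carry chemistry
  (chem_fraction defaults to 0.25, the partial-characterization design
  of a realistic annual campaign: chemical speciation within the 30-h
  sample lifetime is only feasible for a fraction of samples).
* **Concentrations.** Log-normal per compound, exp(N(log_mean, log_sd)),
  thinned by a per-compound detection probability; optional hard caps
  (`max_concentration`) guard extremes. Log-normality gives the
  right-skewed, lower-tail-concentrated shape typical of emission
  mixtures — while the fitting stage still uses truncated Gaussians,
  deliberately exercising the same model misspecification the method
  incurs on real data.
* **Odor concentrations.** Log-normal per sample (default
  exp(N(5.5, 0.8)) ≈ a few hundred ou_E/m³, a typical industrial range).
* **Panel.** Truncated-Gaussian generating laws for N_Y (1–12 yr),
  F_S (40–400 samples/yr) and N_PR (6–14), reflecting the high
  dispersion of part-time panels; 8 panelists, 20 recorded N_PR
  observations each.

The default scenario covers 7 industrial categories totalling 1035
samples; two (wwtp, biofuel) contain no carcinogenic compound so their
IR is structurally not computable. The bundled toxicology table is a
*synthetic placeholder* with order-of-magnitude-plausible values; real
assessments must supply a vetted tox CSV.

What passing tests on synthetic data do show: the fit → simulate →
summarize machinery reproduces closed-form truncated-normal quantiles,
recovers generating parameters, respects truncation/determinism/
linearity contracts, and handles the partial-characterization and
no-carcinogen designs. What they do not show: that any real laboratory's
risk is low — that depends on real chemistry, real OEL/IUR selections
and real survey data.

## Numerical choices and degenerate inputs

* σ = 0 specs are point masses (clamped into [MIN, MAX]); they sample,
  summarize and report without special-casing upstream.
* HI accumulation uses compensated summation in the scalar path; the
  Monte Carlo path accumulates per-compound vectors (error ≪ 1e-12 at
  realistic mixture sizes).
* Quantiles: linear interpolation between order statistics everywhere.
* ΔZ screening uses the plain ratio Z_ITE/Z̄_ITE with a closed bound
  [−ΔZ_max, +ΔZ_max]. For positive thresholds the lower bound is
  vacuous; the screening function is the single seam where a log-scale
  variant could be substituted if a stricter reading of the underlying
  standard is wanted.
* Empty draw sets, empty observation lists, zero/negative odor
  concentrations, unknown units and non-positive OELs raise named
  errors at the boundary rather than propagating NaNs.

## Problem sizes

Defaults were chosen as the realistic study conditions: 1000 Monte
Carlo iterations per category and 5 sensitivity replicates. Reference
comparisons in the test suite use 1e4–1e5 draws, where Monte Carlo
standard errors are small enough to separate genuine defects from
sampling noise at 3-standard-error / 5%-relative tolerances.

## Known limitations

* No chemical-interaction, toxicokinetic or toxicodynamic modelling —
  HI's additivity is a simplification inherited from the hazard-index
  framework itself.
* No inter-compound correlation within an iteration.
* The truncated-Gaussian family is fixed; the sampler interface is the
  seam where a log-normal or bootstrap alternative would plug in.
* OEL authority selection (which short-term limit wins when several
  exist) is delegated to the tox-table author.
* No minimum-dilution-value computation; this package assesses risk, it
  does not derive operational dilution floors.
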