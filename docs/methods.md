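# Methods

## Model structure

A partitioned survival model with three mutually exclusive states —
progression-free (PFS), progressed disease (PD), death — compares
ramucirumab 8 mg/kg (days 1, 8) + paclitaxel 80 mg/m² (days 1, 8, 15) per
28-day cycle, given until progression, against continued oxaliplatin-based
chemotherapy (FOLFOX/CAPOX for up to 24 weeks, fluoropyrimidine alone
thereafter). State occupancy is read directly off the survival functions:
`PFS(t) = S_PFS(t)`, `dead(t) = 1 − S_OS(t)`,
`PD(t) = max(0, S_OS(t) − S_PFS(t))`; cycles where the fitted PFS curve
crosses above OS are clamped to PD = 0 and counted. The cohort starts fully
progression-free.

The horizon is 10 years in 28-day cycles (130 cycles; >99% of the cohort is
dead by then under every shipped curve). One month is 365.25/12 days
throughout.

## Survival models

Five parametric families are supported on a months time scale, under the
conventions standard in survival-extrapolation practice (for the two used in
the base case: log-logistic `S(t) = 1/(1+(t/scale)^shape)`, so the scale is
the median; log-normal `S(t) = 1 − Φ((ln t − meanlog)/sdlog)`). Fitting
maximizes the right-censored log-likelihood by quasi-Newton search on
log-transformed positive parameters with three moment-guided starts; the
exponential MLE uses its closed form (rate = events / follow-up). Model
selection minimizes AIC, with BIC and then parameter count as tie-breaks.
The shipped base-case parameters (e.g. overall-population OS: log-logistic
shape 2.309 / scale 13.051 for switch maintenance, 1.891 / 9.593 for
control) are used as published; they carry no uncertainty ranges and are
held fixed in all sensitivity analyses — a known limitation inherited from
the source parameter table.

Note one internal tension in that table: under the median-at-scale
convention the switch-arm OS median (13.05 months) sits below the trial's
reported 15.8-month median, and the incremental QALY implied by the
published totals (≈0.15) is smaller than what direct integration of the
published curves yields (≈0.19 discounted). The package computes what the
curves imply; reproduction of the published ICERs is therefore expected
within roughly ±15%, not to the cent.

## KM reconstruction

The Guyot algorithm reconstructs one pseudo-patient record per person at
risk from digitized curve coordinates and the numbers-at-risk row. Within
each at-risk interval the number censored is iterated until the implied
at-risk count at the next published time matches exactly, with censoring
spread uniformly inside the interval; events per digitized drop follow from
the running product-limit estimate. In the final interval, censoring uses
the average prior censoring rate, or — when a total event count is
supplied — is adjusted until the event total matches as closely as the
interval allows. Small digitization jitter (survival rising by ≤0.02) is
snapped to monotonicity with a warning; larger rises are rejected as input
errors. Round-trip accuracy on emulated digitizations of synthetic cohorts
(n = 200, 100 points) is better than 0.02 in survival probability;
per-click rounding can still lose a few percent of events mid-curve, which
is inherent to the method.

## Costing conventions

All costs are 2023 USD. Fractional milligrams are priced exactly (no vial
rounding, matching the source's no-wastage assumption). Regimens on 21- or
14-day cycles are aligned to the 28-day model cycle by scaling per-regimen
cost by 28/cycle-days. Administration fees attach per administration day by
route (intravenous fee for IV drugs, injection fee for premedications, none
for oral). Several inputs the source leaves unstated are fixed here as
configurable defaults:

* **Control-arm composition** — 50/50 CAPOX/FOLFOX at guideline doses
  (CAPOX: oxaliplatin 130 mg/m² d1 + capecitabine 1000 mg/m² b.i.d. d1–14,
  q21d; FOLFOX: oxaliplatin 85 mg/m² + folinate 400 mg/m² + 5-FU
  400 + 2400 mg/m², q14d), fluoropyrimidine-only at the same dose after the
  24-week oxaliplatin cap (implemented as a model-time window at day 168).
* **Premedication** — ondansetron 8 mg + dexamethasone 10 mg +
  diphenhydramine 25 mg per paclitaxel administration (conventional doses;
  the unit prices are published but the doses are not).
* **Monitoring** — 1 blood biochemistry + 1 blood routine + 1 urine routine
  per model cycle and an enhanced CT every second cycle, accrued during
  on-treatment (PFS) occupancy.
* **Post-progression** — 58% (switch) / 56% (control) of PD occupancy
  receives irinotecan 150 mg/m² q21d; the remainder receives best
  supportive care per cycle. Subsequent therapy runs for the whole of PD
  occupancy.

Adverse events (grade ≥3, incidence >5%: neutropenia, peripheral
neuropathy, hypertension) contribute a one-off expected management cost and
a utility decrement lasting one model cycle, both applied in the first
cycle.

## Accrual and discounting

Cycle occupancy is the average of the two boundary survival values
(half-cycle correction); discounting uses `(1+r)^(−t)` at the cycle
midpoint, r = 5% (China) / 3% (US). QALYs weight occupancy by utilities
0.797 (PFS) and 0.577 (PD); life-years are reported undiscounted. Terminal
care is charged per new death in the cycle of death. Refining the cycle from
28 to 7 days moves total QALYs by <1%.

## Sensitivity analyses

One-way analysis evaluates the model at each parameter's published low/high
bound (most are ±20%; asymmetric published ranges — e.g. the Chinese
enhanced-CT fee and the PFS utility — are used as printed; the discount
rate is varied 0–8%). The PSA (default 5,000 iterations) samples gamma
distributions for costs, weight and BSA and beta distributions for
utilities and probabilities, independently, moment-matched with mean at the
base value and sd = (high − low)/3.92 (the range treated as a 95%
interval). One published range (Chinese injection-administration fee,
0.158–0.643 around a base of 0.802) excludes its own base value; it is used
as printed, with a warning. The CEAC reports the fraction of draws with
positive incremental net monetary benefit; for two strategies with ΔE > 0
this coincides with the ICER-below-threshold criterion. Threshold pricing
bisects the ramucirumab price multiplier with one frozen draw table
(common random numbers) so the acceptance probability is monotone in price;
the price under study is set deterministically per candidate, not
resampled.

## Synthetic data

The generator emulates a two-arm trial of 144/142 patients with the shipped
base-case curves as truth: OS drawn by inverse-CDF sampling, progression
drawn independently and PFS = min(progression, OS) — the simplest coupling
that guarantees PFS ≤ OS per record; censoring is the minimum of a 36-month
administrative cutoff and exponential dropout (0.01/month). Digitization is
emulated by sampling the KM step function on an even grid with optional
uniform jitter (≤0.005) clipped to monotonicity, plus exact at-risk counts.
It does not emulate accrual dates, per-patient subsequent-therapy
sequencing, or correlated digitization error, so round-trip tests validate
the arithmetic of the pipeline, not the behaviour of manual plot extraction
on real figures.

## Numerical choices and limitations

* Gompertz shapes may be negative (defective survival plateauing at
  `exp(rate/shape)`); likelihood evaluation clips exponents to avoid
  overflow.
* Model-selection ties break by BIC, then by fewer parameters.
* PSA draws use one child generator per parameter from a spawned
  `SeedSequence`, so a parameter's draws are invariant to the composition of
  the sampled set; identical seeds give bit-identical results.
* Survival parameters are excluded from both tornado and PSA (no published
  ranges); structural uncertainty in the extrapolation is therefore not
  propagated.
* Whether the source model applied half-cycle correction, how often it
  billed monitoring tests, and the exact control-arm drug mix are unknown;
  these bound the achievable agreement with the published totals (observed:
  ICERs within ~14%, incremental costs within ~10%).
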