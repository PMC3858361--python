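# Methods

## Model structure

The cohort model has three mutually exclusive states — disease-free
survival (DFS), progressed disease (PS) and death — evaluated at 6-week
cycle boundaries over a 30-year horizon (260 cycles; a 52-week year, so
one cycle is 6/52 ≈ 0.1154 years). All patients start disease-free at
age 60 at the time of surgery.

Occupancy is **partitioned survival**: at cycle boundary *t*,
DFS = S_PFS(t), death = 1 − S_OS(t) and PS = max(0, S_OS(t) − S_PFS(t)).
This construction reproduces both input curves exactly, conserves
probability to machine precision and needs no assumption about the
PS→death transition, which no printed input identifies. Cycles where
the OS curve would fall below the PFS curve are clamped at PS = 0 and
counted on the trace (`n_clamped`; zero for all three strategies here).
An equivalent transition-probability formulation
(p = 1 − S(t+u)/S(t) applied sequentially) is implemented and tested to
agree with the partitioned trace to 1e-12 — the two are algebraically
identical for the DFS compartment.

### Survival inputs

Survivor functions are Weibull, S(t) = exp(−λ·t^γ) with *t in cycles*.
The surgery-only reference: PFS λ = 0.017869, γ = 1.055532; OS
λ = 0.005483, γ = 1.19. Active arms scale λ by the trial hazard ratios
(XELOX 0.56 PFS / 0.72 OS; S-1 0.62 / 0.68), the exact power identity
S^HR for this family. The cycle time unit is pinned by a test: the
reference OS curve evaluated at 260 cycles leaves 98.3% of the cohort
dead at 30 years, consistent with the reported ≈98.9%; month or year
units are off by orders of magnitude.

Two fitting routes support working from data rather than printed
parameters: least squares on the linearised curve
log(−log S) = log λ + γ·log t for summary (Kaplan-Meier-style) input,
and right-censored maximum likelihood (via lifelines) for individual
patient data. AIC/BIC are reported as 2k − 2ℓ and k·ln n − 2ℓ for the
fitted k and n; adjusted R² only for the linearised regression, where it
is meaningful. The estimator behind the published parameters was never
stated; both routes are exposed and the report records which was used.

### Rewards

Per cycle: occupancy at cycle start × reward × cycle length, discounted
by (1.03)^(−t) at the cycle-start time. A half-cycle-correction flag
(trapezoid occupancy) exists and defaults to off. DFS utility is a step
function of years since model start — XELOX 0.68 on [0,5), 0.81 on
[5,10), 1.0 after; S-1 and SO 0.81 on [0,10), 1.0 after — and PS
utility is 0.5 everywhere. The "1–5 years" wording of the source
utilities is read as the first five model years.

## Costing (2010 USD, $1 = ¥6.6515, no inflation adjustment)

Doses are rounded **up** to whole dispensing units per administration
(no vial or tablet sharing — a conservative payer convention) at a body
surface area of **1.72 m²**. BSA is stated nowhere in the source
inputs; 1.72 m² was calibrated once against the reported DFS cost
levels (it reproduces the XELOX and S-1 DFS totals within ~6% and 3%)
and is exposed in the configuration.

- **XELOX** (eight 3-week cycles = 24 weeks = 4 model cycles):
  capecitabine 1000 mg/m² twice daily, days 1–14 (4 × 500 mg tablets ×
  28 administrations) plus oxaliplatin 130 mg/m² day 1 (5 × 50 mg vials
  + one $18.50 infusion fee) per regimen cycle.
- **S-1** (one year of 6-week cycles ≈ 8⅔ model cycles, fractional last
  cycle prorated by week overlap): 40 mg/m² twice daily, days 1–28
  (4 × 20 mg capsules × 56 administrations) per regimen cycle.
- **Adverse events**: the expected cost Σ risk·cost over grade-3/4
  events is charged once in the first cycle (a flag amortises it over
  the treatment window instead; only discount timing changes).
- **Surveillance** (charged to DFS occupants only): XELOX — abdominal
  imaging every 6 months in years 1–3 then yearly (priced as the mean
  of the CT and MRI unit costs, since the protocol says "MRI or CT"
  without proportions), chest radiograph quarterly in years 1–2,
  twice-yearly in year 3, then yearly; S-1 — CT every 6 months in years
  1–2 then yearly, plus six two-monthly laboratory evaluations in year
  1. The surgery-only cohorts were surveilled like their trial
  counterparts; this model assigns them the S-1-arm schedule, which
  lands near the reported SO DFS cost level.
- **Progressed state** (identical across strategies): 25% of patients
  receive weekly paclitaxel 80 mg/m² (5 × 30 mg vials + infusion fee,
  3 infusions per 4-week block, time-scaled to the 6-week cycle) and
  75% receive supportive care at $1,415.4 per 3 weeks — $2,793 per
  occupant-cycle at default prices. "3 times per week" in the source
  description is read as the standard days-1/8/15 weekly schedule.

## Economics

CER = C/E per strategy; ICER = ΔC/ΔE on unrounded totals. Comparisons
with negative increments are labelled `dominant`/`dominated` rather than
printed as negative ratios. The frontier removes strictly dominated
strategies, then extendedly dominated ones (keeping ICERs strictly
increasing; collinear strategies are retained, exact duplicates
tie-break by name), and is invariant to input order.

## Sensitivity analysis

**One-way (tornado)**: all 29 inputs with ranges, plus the discount rate
over the 0–8% guideline band, varied one at a time to their range ends
with the rest at their medians; the raw incremental ratio for S-1 vs
XELOX is recorded at both ends and entries are sorted by spread.

**PSA** (1,000 replicates): each replicate re-samples all 29 inputs
independently and re-runs costing and utilities over the fixed traces.
Replicate *i* draws from `default_rng([seed, i])`, so runs are
reproducible and parallelisable. Acceptability curves report, per
threshold, the fraction of replicates in which each strategy attains the
maximum net monetary benefit (ties, a measure-zero event, go to the
fixed SO < XELOX < S-1 order). A 95% confidence ellipse on the
incremental cost-effect plane is computed from the sample moments at the
chi-square(2) quantile.

**Distributions.** The sources quote a median, a range and a family
(lognormal/gamma/beta) but not the mapping between them. This package
reads the range as a 95% interval: sd = (high − low)/3.92 on the natural
scale, with mean set to the median (for the lognormal, μ = ln median
and σ = (ln high − ln low)/3.92). Draws are confined to the family's
support, never clipped to the range; infeasible beta moments fall back
to uniform(low, high) with a warning. **This mapping is the dominant
judgement call in the probabilistic results**: plausible alternatives
(range as min–max of a uniform, range as ±2 sd of the underlying
normal, method-of-moments on the midpoint) change acceptability
probabilities by several percentage points.

## Synthetic data

`simulate_ipd` draws event times by inverse transform,
T = (−ln U/λ)^(1/γ), with administrative (type-I) censoring at a fixed
time — enough to exercise the fitting stage end-to-end with known
ground truth. It does not emulate staggered accrual, loss to follow-up
or covariate-dependent hazards, so passing recovery tests demonstrate
estimator correctness, not robustness to real trial follow-up
structure. `trial_fixture` builds small summary curves from the same
Weibull family pinned exactly to the four arms' printed 3-year
PFS/OS landmarks; all outputs are labelled SYNTHETIC.

## Numerical choices

- Occupancy conservation enforced at 1e-12; death monotonicity checked.
- Surveillance episodes at time *t* are charged to the cycle whose
  interval (k·c, (k+1)·c] contains *t*; episodes beyond the horizon are
  dropped, those at exactly 30 years fall in the final cycle.
- S(t) underflow in the transition-probability route returns 1 with a
  warning.
- Dose rounding guards against float droop on exact unit multiples.
- Problem sizes: 260 cycles per trace, 1,000 PSA replicates, n = 10,000
  subjects for parameter-recovery tests and 100,000 draws for sampling
  moment tests — the full analysis runs in about two seconds.

## Known limitations and discrepancies

The original implementation's internal state structure is not fully
recoverable from its printed inputs, and its progressed-state occupancy
is demonstrably smaller than the partitioned-survival construction
implies: its reported PS QALYs correspond to discounted PS person-years
of about 2.28/1.02/1.98 (SO/XELOX/S-1), whereas the partitioned trace
built from the same printed survival parameters gives 2.57/1.65/2.45,
and its reported 30-year death fractions (95.7–98.9%) all exceed
1 − S_OS from the printed parameters (93.8–98.3%). Its progressed
cohort therefore died faster than the OS curve — an unstated PS→death
assumption this package deliberately does not reverse-engineer (the
rates required, implying 6–8-year mean post-progression survival, have
no principled clinical source). Consequences, all quantified by the
acceptance tests: DFS QALYs and DFS costs reproduce closely; total
QALYs run ~3–5% high; PS (hence total) costs and the pairwise ICERs
deviate beyond their documented bands (e.g. XELOX total $56.3k vs the
reported $44.7k; S-1 vs XELOX ICER $46.9k vs $58.8k). The probabilistic
acceptability of XELOX vs S-1 also runs ~12 points above the reported
75.8%, driven jointly by the PS discrepancy and the undocumented
median-range-to-distribution mapping. Qualitative conclusions — SO
dominated, frontier XELOX→S-1, XELOX optimal at the $13,527 threshold
with the preference switching to S-1 in the $30–60k band, utilities
dominating the tornado — all reproduce.

Other limitations: no background (other-cause) mortality beyond the OS
curve; no hospitalisation costs, dose reductions or discontinuations;
independence of all sampled parameters; no value-of-information
analysis.
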