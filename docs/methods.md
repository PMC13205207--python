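# Methods

## Model structure

The model couples a one-off decision tree to an annual-cycle Markov cohort
model, the standard architecture for screening evaluations that separate
short-term diagnostic pathways from long-term disease dynamics.

**Decision tree.** Each child is screened once at t = 0.  Stage 1 (WHtR ≥
0.48) flags a fixed 22.6% of the cohort.  The prevalence among
WHtR-positives is derived from the population prevalence π(age), the
stage-1 sensitivity σ₁, and the positivity ρ₊: π_cond = π·σ₁/ρ₊.  σ₁
defaults to 1.0 — the anthropometric cut-off is treated as capturing all
cases, so no diseased child is lost at stage 1 — and is configurable; if a
configuration implies π_cond > 1 the run aborts with a configuration error
rather than silently capping (capping would delete diseased mass and break
the arm-fraction accounting).  Stage 2 applies the selected test's
sensitivity/specificity to the WHtR-positive subgroup, yielding TP/FN/FP/TN
fractions; WHtR-negatives split into diseased/healthy remainders.  Screening
is one-off: no repeat rounds, no uptake below 100%, no WHtR measurement
error.

**Management.** Second-stage positives (TP + FP) enter the
lifestyle-modification programme.  TPs split into responders (response rate
ρ = 0.40) who follow the intervention transition regime, and non-responders
on natural history; both accrue programme costs, as do FPs (who are
disease-free, never transition, and accrue the disease-free utility).
FN and WHtR-negative diseased children follow natural history untreated.
All diseased slices start from the baseline fibrosis-stage split
(88.5 / 5.2 / 3.5 / 1.6 / 1.2% over F0–F4).

**Markov model.** Five states F0–F4 (F4 read as compensated cirrhosis),
annual cycles, 10-year horizon, deterministic life-table bookkeeping.  Each
cycle a child remains, progresses one stage, or regresses one stage —
matrices are tridiagonal and row-stochastic by construction and validated
as such.  Natural regression is 6%/year in every non-F0 state; responders
regress at 27.7%/year (taken as an annual probability) with progression
unchanged.  There is no death or other exit state: over 10 childhood years
background mortality is negligible, and HCC/decompensation/transplant are
deliberately out of model scope.  Mass is therefore conserved exactly and
is asserted at every cycle.  No half-cycle correction is applied: states
are read at cycle boundaries and utilities accrue end-of-cycle
(t = 1..10), consistent with the life-table convention; screening costs
fall at t = 0 undiscounted.

## Parameters

All inputs live in one registry (`masld_cea.params`), serializable to the
shipped `configs/base_case.yaml`.  Key values (2019 USD; 95% CIs in
parentheses):

| Input | Value | PSA distribution |
|---|---|---|
| Ultrasound SE / SP | 0.52 (0.41–0.64) / 0.96 (0.91–0.99) | Beta |
| FibroScan SE / SP | 0.72 (0.64–0.79) / 0.98 (0.97–0.98) | Beta |
| MRI-PDFF SE / SP | 0.95 (0.92–0.97) / 0.92 (0.77–0.98) | Beta |
| Utilities F0 / F1=F2 / F3 / F4 | 0.95 / 0.85 / 0.73 / 0.66 | Beta (F1,F2 joint) |
| Progression boys (F0→1…F3→4) | 0.4 / 3.3 / 3.3 / 3.4 %/y | Beta |
| Progression girls | 0.3 / 2.8 / 2.8 / 2.8 %/y | Beta |
| Regression (natural / treated) | 6% / 27.7% per year | fixed |
| Response rate ρ | 0.40 | fixed (scenario 0.30–1.00) |
| Costs: exam / US / FibroScan / MRI / bloods | 2.9 / 16.5 / 13.0 / 87.0 / 22.5 | fixed |
| Programme fixed + variable | 10.5 + 21.7 per participant-year | fixed |
| Discount rate | 3%/year (scenarios 0, 5%) | — |
| WTP thresholds | $30,584.0 and $71,415.5 per QALY | — |

Beta distributions are fitted by method of moments with
σ = (CI_high − CI_low)/(2·1.96): ν = m(1−m)/σ² − 1, α = mν, β = (1−m)ν.
This preserves the analytic mean exactly and is the standard CEA practice
when only a mean and interval are reported; asymmetric intervals enter only
through σ (no CI-matching optimization).  A zero-width interval signals a
fixed value; an implied variance ≥ m(1−m) is rejected as unfittable.

**Cost conventions.** The routine physical examination ($2.9) is charged to
every child under S1–S3 and to no one under S4.  The blood biochemical
panel ($22.5) is charged to all WHtR-positives by default (the disease
definition requires cardiometabolic criteria at the second stage); a config
switch restricts it to second-stage positives.  Programme costs
($32.2/participant-year, fixed + variable) recur for every programme
participant — including false positives and non-responders — each cycle
for the full horizon by default; `program_duration_years` shortens the
stream.  Recurring for the horizon is the conservative reading given that
the programme carries all modelled benefit.

## Synthetic cohort and prevalence

The cohort defaults to 100,000 children, uniform over ages 6–14, 50/50
sex split (composition configurable); strata get integer head counts by
largest-remainder rounding.  The age-specific MASLD prevalence is a
**synthetic** logistic-linear profile, logit π(a) = logit(0.05) +
0.08·(a − 6), i.e. 5% at age 6 rising to ~9.1% at 14 — a plausible shape
for urban Chinese schoolchildren given obesity-linked age trends, chosen
once and not tuned.  Any user-supplied per-age mapping can replace it in
the config.  Consequently the synthetic runs emulate the decision *problem*
faithfully (cascade arithmetic, dynamics, economics) but not any particular
population's absolute burden: passing tests establish internal correctness
and directional behaviour, not the dollar figures a real prevalence profile
would produce.

## Validation design

* **Microsimulation oracle.** An independent per-individual simulator draws
  each child's initial stage and annual transitions by categorical sampling
  from the same matrices.  At n = 2,000 and fixed seeds, per-(cycle, stage)
  occupancy agrees with the cohort engine within 3 binomial standard errors
  (computed under the engine's expected occupancy) across natural,
  intervention, and every scenario-flag regime, as do discounted QALYs.
  With ~55 positively correlated cells per run, a marginal 3-SE excursion
  in one cell is an expected event for some seeds even for an exact engine;
  the unit-level variant of the check therefore requires ≥96% of cells
  within 3 SE with a hard 4-SE cap, while the end-to-end suite retains the
  strict all-cells form.
* **Matrix-power oracle.** In the age-homogeneous base case the horizon
  evolution must equal the 10th matrix power applied to the seed vector.
* **Arithmetic anchors.** The published base-case table and pairwise
  increments (`masld_cea.benchmarks`) are used only for
  internal-consistency checks (Eq. ICUR on printed increments; adjacency
  differences), never as targets to fit.

## Sensitivity analyses

One-way bounds default to the printed 95% CI endpoints; inputs without
intervals use ±20% (probabilities clipped to [0, 1]); bounds violating a
structural invariant are skipped with a logged warning.  Scenarios:
discount 0%/5%; ρ ∈ [0.30, 1.00]; treated regression scaled by 0.75 in
F3/F4 (reduced responsiveness in advanced fibrosis); adolescent modifiers
(+25% progression, −25% regression at ages ≥ 15 — direction is
established, magnitude is a configurable package choice and is always
reported alongside results); 1- and 5-year horizons.  Adolescent modifiers
apply to both regimes, treating them as a natural-history property of
adolescence rather than a treatment interaction.  Two-way analysis
overrides one test's SE/SP per grid cell, comparators at base case.

PSA (default 1000 iterations) draws all 18 Beta inputs independently —
costs and no-CI probabilities stay fixed; correlations are not modelled —
with all four strategies evaluated on the common draw so per-iteration
frontier comparisons are coherent.  Structurally invalid draws are rejected
and redrawn with a logged count (not triggerable under the default CIs).
CEACs use a $0–100,000 grid in $1,000 steps; the per-iteration winner is
the NMB maximizer with ties broken toward lower cost.  Everything is
reproducible from a single seed via named substreams.

## Numerical conventions

* Frontier: strict dominance removed first, then extended dominance by
  iterated violation of increasing incremental ICURs; the threshold
  decision (last frontier ICUR ≤ WTP) is asserted equal to the NMB
  maximizer, with a 1e−9 relative guard against float cancellation only.
* Equal-QALY comparisons return an explicit undefined-ICUR flag, never a
  division error; cheaper-and-better / costlier-and-worse quadrants are
  flagged dominant/dominated since the raw ratio misleads there.
* Tolerances: state vectors and arm fractions conserve mass to 1e−12
  (1e−9 where float accumulation across strata applies); matrices are
  validated tridiagonal row-stochastic at 1e−9.
* Problem sizes in the shipped analysis runs — 2,000 individuals for the
  microsimulation cross-check, 1000 PSA iterations (300 for the CEAC shape
  test in the suite), 100,000-child cohort — are the package's analysis
  defaults; the cohort engine itself is deterministic so cohort size only
  scales totals linearly.

## Known limitations

* No mortality, HCC, decompensation, transplantation, tunnel states, or
  extra-hepatic complications (diabetes, cardiovascular disease); the
  10-year childhood horizon understates lifetime benefit.
* The 27.7% treated regression is applied as an annual probability; if the
  source estimate were per-96-weeks the treatment effect would be modestly
  overstated (an alternative annualization is a config change away).
* Utilities derive from adult populations; F1/F2 share one estimate.
* Screening uptake, adherence, and waning programme effectiveness are not
  modelled; false-positive children are assumed to complete the programme.
* Absolute results are conditional on the synthetic prevalence profile;
  only worked-example arithmetic and directional/structural findings are
  asserted against published figures.
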