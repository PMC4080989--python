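# Methods

## Assay model

The ATP-TCA reads cell viability as luciferin–luciferase luminescence
proportional to cellular ATP. The package models one 96-well plate as up
to four conditions (drugs or fixed-ratio combinations), each with three
replicate wells at six doubling dilutions covering 200%–6.25% of the
test-drug concentration (TDC, chosen as a clinically achievable level),
plus one control row: medium-only wells (MO, the 0% inhibition
reference) and maximum-inhibitor wells (MI, complete kill, the 100%
reference). Inhibition for a test reading is
`(1 − (Test − MI)/(MO − MI)) × 100` with MO/MI the per-plate control
means; the quantity is invariant to the instrument's emission scale, so
absolute count levels never matter downstream.

Key conventions, all recorded in the run manifest:

- **Control aggregation.** MO and MI wells are averaged per plate. A
  control reading farther than 3 SD from the mean of the *other* wells
  in its group is dropped with a warning. The leave-one-out form matters:
  for nine or fewer wells a single aberrant reading inflates the pooled
  SD enough that an in-sample 3-SD rule can never fire (the maximum
  standardized deviation of n points is (n−1)/√n ≈ 2.04 at n = 6), so
  the rule is implemented against the remaining wells. At 8% replicate
  CV the rule trims roughly one well per few plates; since only means
  enter the analysis the effect is negligible, but it protects against
  genuinely failed wells. MO ≤ MI raises a control-failure error naming
  the plate — no inhibition value is computable from an inverted window.
- **Clipping.** Inhibition is stored unclipped (noise can push readings
  above MO or below MI) and clipped to [0, 100] before IndexSUM and IC
  interpolation, keeping the index inside its nominal [0, 600] bounds.
- **Replicate CV.** Computed on raw replicate counts (SD/mean, sample
  SD), where the variability physically arises; a switch (`cv_on`)
  moves it to derived inhibition values instead. The QC rule flags any
  step whose CV exceeds the limit (default 10%) and fails the profile if
  any step is flagged. Note that the sample CV of triplicates is itself
  noisy (SD ≈ CV/2), so at a true CV of 8% a six-step profile fails this
  strict rule more often than not; the flag marks steps to inspect, and
  the limit is configurable.
- **ATP standard curve.** Ordinary least-squares line (free intercept)
  through the supplied (amount, counts) pairs, inverted for QC readouts;
  readings outside the calibrated count range are flagged. The curve
  never enters the inhibition arithmetic, which is control-normalised.

## Sensitivity statistics

**IndexSUM** is `Σₖ (100 − clipped inhibitionₖ)` over the six steps:
0 = complete inhibition everywhere, 600 = none anywhere, and the index
is exactly 600 minus the summed clipped inhibition. An agent is *active*
iff IndexSUM < 300 (strictly; 300 itself is inactive), equivalent to
mean inhibition above 50% across the tested range.

**IC50/IC90** use first-crossing interpolation: scanning from the lowest
concentration upwards, the first bracket where clipped inhibition
crosses 100·F is interpolated linearly in log₂(concentration) — the
natural axis for a doubling design. Profiles already above the target at
the bottom step are censored "< bottom"; profiles that never reach it,
"> top". Censored values carry the bounding concentration and side and
propagate as "not estimable" into combination analysis; no bound is ever
substituted for a dose. Non-monotone profiles take the first crossing;
no isotonic smoothing is applied by default. A smooth alternative
backend fits a Hill curve `I(c) = Imax·cʰ/(EC50ʰ + cʰ)` (bounded
least squares on (Imax, log₁₀EC50, h); flat profiles are reported as
degenerate, never silently defaulted) and inverts it analytically;
interpolation remains the default because it makes no shape assumption.

## Combination analysis

A combination is a fixed-ratio ray: step k of the mixture pairs step k
of each drug's own series (simultaneous addition), so cA/cB is constant.
The mixture profile is indexed on the A-component concentration axis;
its F crossing is located with the same ICF estimator and split into
component doses by the ratio. The Chou–Talalay index
`CI = dA/DA + dB/DB + α·dA·dB/(DA·DB)` defaults to α = 0 (mutually
exclusive; α = 1 is a flag), and classification assigns CI < 0.8 to
synergy, CI > 1.2 to antagonism, and the closed interval [0.8, 1.2] —
including both printed boundaries — to additive. CI is symmetric under
relabelling (A,B) → (B,A), and the α = 1 value is never below the α = 0
value.

## Synthetic data generator

Ground truth is a Hill response per (cell line, drug). Expected counts
per well are `MI + (MO − MI)·(1 − I/100)`; replicates add multiplicative
Gaussian noise with constant CV (default 8%, inside the assay's < 10%
working band), truncated at zero. The noise law is a modelling choice —
only a CV bound is known for the real assay, not a distribution.
Controls sit in row H (MO H1–H6, MI H7–H12); emission means default to
50,000 (MO) and 500 (MI) counts, an arbitrary scale since the analysis
is scale-invariant (and tested as such). All draws derive from a single
seed; identical seeds give bit-identical tables.

Mixtures solve the generalised Loewe equation
`dA/DA(I) + dB/DB(I) = ρ` for the effect I at each ray step (bisection
over I; a drug's equipotent dose above its Imax is infinite, the usual
partial-agonist convention, and a failed bracket raises rather than
imputing). ρ = 1 is exact Loewe additivity — the measured mixture then
sits on the isobole, so the recovered CI50 equals 1 up to interpolation
error; ρ < 1 shifts potency upwards and is recovered downstream as
CI ≈ ρ for equal-shape pairs. For unequal Hill slopes the mixture curve
is no longer Hill-shaped and the six-point log-linear interpolation
carries more error; recovered CI50 stays within ±0.15 of truth in the
tested parameter ranges.

**Isogenic preset.** Six MCF10a lines (parental, PIK3CA H1047R, PIK3CA
E545K, EGFR ΔE746-A750, BRAF V600E, AKT E17K) × four inhibitors with
TDCs of 1.0, 3.25, 1.1 and 1.0 µM (gefitinib, erlotinib, ZSTK474,
sirolimus), so each series spans the intended tested ranges. Per-drug
curve shapes are fixed (Imax 100 for the EGFR/PI3K inhibitors; Imax 85,
shallow slope for sirolimus, reflecting partial mTOR inhibition), and
each line's EC50 is obtained by numerically inverting the noiseless
IndexSUM to a target value — the targets encode the panel's sensitivity
ordering (PIK3CA mutants most sensitive to EGFR/PI3K inhibition with
E545K ahead of H1047R, every mutant more gefitinib-sensitive than
parental, AKT E17K slightly erlotinib-resistant, BRAF V600E most
sirolimus-resistant). All four combinations use ρ = 0.5; analytically
the mixture then beats the better single agent by at least ~34 index
units in every line, about 3 SD of the index under 8% noise, so the
qualitative orderings survive the default noise level.

What the generator does **not** emulate: plate-position (edge/gradient)
effects, systematic pipetting bias, batch drift between plates, cell
seeding variability, or mechanistic pathway crosstalk. Passing tests
therefore validate the estimators under the assay's idealised error
model, not robustness to structured artefacts in real plates.

## Numerical choices and problem sizes

Interpolation crossings hit grid points exactly (an inhibition equal to
the target at a step returns that step's concentration). The Loewe
bisection uses brentq with 1e-12 tolerances; the EC50-from-index
inversion is a brentq root find on log₁₀(EC50) over ±8 decades and is
infeasible below the index floor 600 − 6·Imax, which raises. Hill fits
use analytic-friendly starting values (max inhibition, first half-max
concentration, slope 1).

Test-suite simulation sizes — 200 noiseless Loewe pairs, 200 noisy
recovery plates, one full panel per seed, 1000 random profiles against a
10⁵-point grid oracle — run in a few seconds total and give the binomial
margins quoted in the tests (e.g. ≥ 90% recovery at ±25% with 200
trials).

## Known limitations

- CI requires every dose estimable at the effect level; strongly
  synergistic combinations can push the mixture's 50% crossing below the
  lowest tested dose, censoring CI50 even though synergy is visible in
  the index — a property of the fixed six-step window, faithfully
  reported rather than extrapolated.
- No confidence intervals on IC or CI values; the assay design
  (triplicates at six doses) does not support them well, and none are
  defined for the summary statistics implemented.
- The activity and synergy thresholds (300; 0.8/1.2) are the assay's
  conventions, not estimated quantities.
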