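# Methods

This note documents the models behind `waitline`, the parameters that
matter, the calibration choices, and what the synthetic data can and
cannot show.

## Tumor kinetics

Tumors are modelled as spheres of diameter *d* mm at constant
cell-packing density ρ (default 10⁹ cells/cm³, the standard convention
that a 1 cm³ tumor holds ~10⁹ cells), so *N = (π/6)(d/10)³ρ*. This
density reproduces the two anchor points the analysis rests on: the
mammographic detection threshold at ~3 mm ↔ ~10⁷ cells and the
palpability threshold at ~10¹⁰ cells ↔ 26.7 mm (within the quoted
25–30 mm range). Cell counts are taken as primary for the thresholds;
diameters are derived.

Growth between the thresholds is exponential with a constant
volume-doubling time. The threshold sizes pin down only the endpoints of
growth, not the law; exponential growth with a single doubling time is
the simplest law consistent with them, and is this package's choice.
The default doubling time, 168.5 days, is calibrated so the
detection→palpability sojourn, *T_d·log₂(10³) ≈ 4.6 years*, matches the
screening-utility ceiling the analysis uses. Both parameters are
config-overridable (`tumor_model:` block). Gompertzian or
stage-dependent growth is deliberately out of scope.

## Poisson metastasis model

Metastatic seeding is a Poisson process whose mean grows with the
accumulated cell count, μ = N/P; the probability that at least one
metastasis exists is 1 − e^(−N/P). P (cells per expected metastatic
event) is not observable directly and is **calibrated** against the
stage-specific probabilities observed under the reference 32-month
waiting list (T1B 3%, T1C 20%, 59% for T2 truncated at palpability):

* each TNM band (T1A 1–5, T1B 5–10, T1C 10–20, T2 20–26.7 mm) is
  represented by its **geometric** midpoint diameter — cells scale with
  d³, so the geometric mean is less size-biased than the arithmetic one;
* the objective is least squares on the probability scale (the observed
  table contains exact 0% entries, which log-odds could not represent);
  a 0% observation contributes a one-sided penalty on any positive model
  probability;
* with a single informative pair the closed form P = −N/ln(1−p) is used.

The default calibration yields P ≈ 7.14×10⁹ cells with residuals below
1.5 percentage points on every band (in-sample column ≈ 2.6 / 18.7 /
59.6%).

**Waiting-time effect.** Under a strategy with waiting time W months,
the size detected in a band is the reference-strategy size advanced by
(W − W_ref)·`months_scale` months of exponential growth (negative for
shorter waits, i.e. the tumor is caught earlier). This mechanism is a
modelling choice of this package — the simplest one consistent with
probabilities that fall as waits shorten — not an empirical statement;
`months_scale` (default 1.0) lets users attenuate it. The model
guarantees elementwise monotonicity of the probability columns in
waiting time. The probabilities it produces for the 22- and 16-month
strategies are qualitatively close to, but not identical with, the
reference analysis's non-calibration columns, whose construction is not
fully specified; only the calibration column and the monotone ordering
are treated as reproducible.

Bands at or beyond the palpability diameter carry a sentinel instead of
a probability: a palpable tumor defeats screening as an early-diagnosis
tool.

**Intervals.** The 95% intervals on probabilities are Wilson score
intervals at an effective n of 242 (the registry size); the original
interval construction is unstated, so this is a documented default, not
a reproduction.

## Cost model

Currency is held as `decimal.Decimal`, exact at cent resolution; all
ledger identities (margin = revenue − cost, variation = cost − reference
cost) hold to the cent by construction.

Daily cost composes per-team staff cost (€608.28/team over the 5 working
hours) × teams, plus the goods/services (€128.59), overheads (€92.65)
and equipment (€30.82) daily shares. Daily revenue is exams/day × the
blended tariff €87.00 + 0.35 × €36.15 = €99.6525 (every exam earns the
fee; the ticket accrues on the 35% paying fraction). The 3-year horizon
is 728.37 working days (~242.8/year), back-solved from the hypothetical
strategies' 3-year totals over their daily costs.

Several figures in the source accounts do not decompose from the
components: the 22-month daily cost (€2,715.99 exceeds the composed
three-team figure), the 80-exam daily revenue (€7,936.05 vs the blend's
€7,972.20), the current strategy's 3-year total (€1,069,687.68 vs the
horizon's €1,069,691.47) and its unit cost (€34.42 vs 1,468.61/40 =
€36.72). Per-strategy **overrides** in the configuration are the
supported path for the first three; the unit cost is always computed and
the discrepancy flagged in the ledger, never silently matched. With
`use_printed_overrides: false` everything is recomposed from components
instead. Depreciation schedules, payroll detail and discounting are out
of scope (the analysis applies no discounting).

## Effectiveness and QALYs

Analysis horizon: 3 years from diagnosis, stratum-level (metastatic vs
non-metastatic), undiscounted. LY = incident patients × life expectancy;
LYG is the LY difference versus the current strategy. QALYs weight LY by
utilities 0.696 (first year, non-metastatic), 0.779 (subsequent years),
0.685 (metastatic, all years); the non-metastatic first-year share is
min(1, LE)/LE of the life-years.

The shipped survival table (`data/survival_synthetic.csv`) is a
**synthetic stand-in** for SEER stage-specific survival: its two life
expectancies (metastatic 1.20316 y, non-metastatic 2.61696 y) are free
parameters solved in closed form (a 2×2 linear system on the incident
counts) so the pipeline's LYG totals land exactly on 47.8 and 103.8.
Users with real SEER-derived values should substitute them via
`effects.survival_table`. The reported stratum QALYs carried in the
configuration are internally inconsistent with any single non-metastatic
life expectancy at one printed decimal (the 22-month and 16-month strata
imply disjoint rounding windows); with `use_printed_overrides` on
(default) the downstream QALY/ICER accounting uses those reported strata
as inputs, and with it off the computed route deviates from them by at
most 0.3 QALY.

## ICER and ranking

ICERs are pairwise against the current strategy only — no efficiency
frontier. A zero QALY difference yields an explicit undefined-ICER
signal, never a number. Dominance is classified from the signs of the
deltas (cheaper-and-better dominant, dearer-and-worse dominated).
Ranking places dominant strategies first, then trade-offs by ascending
ICER (stable sort; equal ICERs flagged as ties); an optional
willingness-to-pay threshold adds verdicts. Output uses locale-neutral
decimal points throughout.

## Synthetic cohort

The generator emulates the 2019 registry (n = 242): marginal frequencies
for T-stage (20/65/95/59/3), nodal status (154/88), histology
(189/44/5/2) and grade (79/109/47, renormalized over the 235 graded
patients). Diameters are drawn log-uniformly within each band
(consistent with exponential growth through the band). Attributes are
sampled **independently** — only marginals are published — so joint
stage×grade×histology structure, screening-round dynamics and
patient-level survival are not emulated; passing tests show marginal
fidelity and determinism, not clinical realism. Metastatic status is
Bernoulli per patient with probability pr_met(N(diameter)).
`scale_to_strategy` rescales a spec to a strategy's 3-year volume
(30,000 / 45,000 / 60,000) and can optionally shift the stage mix toward
smaller stages for shorter waits by re-binning band midpoints through
the growth model (off by default).

## Numerical choices and problem sizes

* Calibration: bounded scalar minimization on log₁₀P (tolerance 1e-12);
  deterministic.
* Probabilities are clipped just below 1; `expm1` avoids cancellation at
  small μ.
* Cohort sampling uses `numpy.random.default_rng(seed)`; the pipeline
  stamps every output with the seed and a config hash, and identical
  seeds reproduce byte-identical bundles.
* Test-suite problem sizes: cohorts up to 10⁵ patients for
  law-of-large-numbers checks, 40 replicate calibrations for the
  noisy-recovery check; the whole suite runs in a few seconds on one
  CPU.

## Known limitations

* The waiting-time→size mechanism and the exponential growth law are
  modelling choices; alternatives (stage-duration models, Gompertz)
  would change the non-reference probability columns.
* The survival fixture is calibrated, not sourced from SEER; LY/LYG
  levels inherit its assumptions.
* Independent-marginal cohorts cannot exhibit stage-histology
  correlations.
* Accounting overrides reproduce the source ledger exactly but leave the
  underlying component-level discrepancies unexplained; they are flagged
  in every report.
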