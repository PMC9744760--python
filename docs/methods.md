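# Methods

This note documents the statistical model behind `summr`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Two-sample MR model and assumptions

The package estimates the causal effect &beta; of a continuous exposure
(variance standardized to 1) on an outcome from per-variant summary
associations estimated in two non-overlapping samples.  Valid instruments
must be (1) associated with the exposure, (2) independent of confounders,
and (3) affect the outcome only through the exposure.  The estimators relax
(3) in different ways:

| Estimator | Consistent when | Notes |
|---|---|---|
| IVW (primary) | all instruments valid | multiplicative random-effects SE by default |
| MR-Egger | InSIDE holds (direct effects independent of instrument strength) | intercept estimates mean directional pleiotropy |
| Weighted median | valid instruments carry ≥ 50% of weight | bootstrap SE |
| MR-PRESSO-corrected IVW | pleiotropy confined to detectable outliers | simulation-based test |

All p-values use the normal approximation z = &beta;/se.  Wald-ratio
weights are first-order (exposure-side uncertainty ignored), the common
convention; second-order weights are available via `second_order=True` but
off by default.  "Random effects" IVW means multiplicative overdispersion —
the fixed-effect SE scaled by max(1, &radic;(Q/(J−2))) — not an additive
between-SNP variance component.

## Instrument processing

* **Selection**: strict p &lt; 5&times;10⁻⁸ (a variant at exactly the
  threshold is excluded).
* **Clumping**: greedy by ascending p, ties broken by variant id so output
  is deterministic; an index variant removes same-chromosome variants within
  10,000 kb having r² ≥ 0.001 with it.  Cross-chromosome pairs are never
  clumped regardless of recorded r².  Without an LD matrix the function
  degrades to distance-only pruning and warns loudly.
* **Harmonization**: allele swaps negate the outcome effect and reflect its
  EAF; strand complements relabel via A&harr;T, C&harr;G; palindromic (A/T,
  C/G) variants with exposure EAF in [0.42, 0.58] are excluded (window 0.08,
  configurable — the conventional choice, since no sharp rule exists), the
  rest are oriented by matching EAF sides with ties at exactly 0.5 treated
  as the upper side.  Records are finally oriented so the exposure effect is
  positive; this makes "directional" pleiotropy a well-defined concept in
  everything downstream.  Exclusions are data (reported with reasons), never
  silent.
* **Strength screening**: per-variant R² and F are reported, with F &lt; 10
  flagged weak.  Weak instruments are *reported, not dropped* by default
  (`drop_weak=True` to exclude), because screening-and-reporting is the
  common practice and silent exclusion would hide selection decisions.
* **Power**: `required_sample_size` / `power_at_n` implement the standard
  binary-outcome normal approximation
  N = (z<sub>1−&alpha;/2</sub>+z<sub>pow</sub>)² / (b²·R²·K(1−K)).  The ceil
  is taken after shrinking by a 10⁻¹² relative guard so float roundoff
  cannot bump an exact integer boundary to the next integer.

## MR-PRESSO implementation

The observed statistic is the weighted RSS of each variant around the
leave-one-out fixed-effect IVW slope fitted without it.  Null replicates
redraw both sides parametrically (exposure effects around their estimates,
outcome effects around the leave-one-out predictions) and recompute the RSS
by the same recipe, including re-deriving the leave-one-out slopes from the
simulated draws.  P-values use the add-one convention
(1+#{RSS* ≥ RSS})/(n_sim+1), so the smallest attainable p is 1/(n_sim+1) and
the test can never report 0.  The per-SNP outlier test runs only when the
global test rejects (default &alpha; = 0.05) and is Bonferroni-adjusted by
the number of instruments; note that with J instruments the outlier test
needs n_sim &gt; J/&alpha; − 1 to be able to reject at all (the default
n_sim = 1000 suffices for J ≤ 49 at &alpha; = 0.05).  The simulation stream
is keyed to variants in sorted-id order, so results are invariant to record
order.  When nothing is flagged, the "corrected" estimate is defined as the
headline IVW estimate (bitwise identical), mirroring how an
outlier-corrected row is reported alongside IVW even when no outliers are
removed.  The distortion test is out of scope.

## Synthetic-data generator

`simulate_two_sample` emulates the summary-level structure the estimators
assume.  Defaults describe a large education-to-disease style design:

| Parameter | Default | Meaning |
|---|---|---|
| `n_snps` | 306 | instruments |
| `n_exp` | 1,131,881 | exposure GWAS sample size |
| `n_out` / `case_fraction` | 121,885 / 12906/121885 | outcome GWAS size and case fraction |
| `causal_beta` | ln 0.72 | true log-OR per SD of exposure |
| `total_r2` | 0.01 | summed instrument R² (exact by construction) |
| `eaf_range` | (0.05, 0.95) | uniform effect-allele frequencies |

`total_r2` = 0.01 makes the default design self-consistent with the power
module (80% power at OR 0.72 needs N &asymp; 77k &lt; 121,885) while keeping
every genome-wide-significant instrument strong (F &gt; 29); it is a
stand-in, not an estimate of any particular trait's architecture.  True
exposure effects are standard-normal draws rescaled so the realized R²
equals `total_r2` exactly.  Standard errors use the standard approximations
1/&radic;(2Nc) and 1/&radic;(2NK(1−K)c), c = p(1−p); observed effects add
independent normal noise in the two samples.  P-values are floored at
10⁻³⁰⁰ so the (0,1] invariant survives the noiseless limit.

Direct (pleiotropic) effects are defined **relative to the
exposure-increasing allele** — allele coding is arbitrary, so a "directional"
mean pleiotropic effect is only meaningful in that frame.  Outlier variants
that are not otherwise pleiotropic get a direct effect of
`multiplier`&times;their outcome-association SE (so a 10&times; outlier is a
10-SE residual, unambiguous by construction); pleiotropic outliers have
their drawn effect multiplied.  Variants associated with the outcome only
(`n_outcome_specific`, default effect 0.15 ± 0.02 log-odds with random sign)
give the reverse direction instruments to select.  Per-SNP randomness is
keyed by (seed, variant index): enlarging the panel never reshuffles earlier
variants.  LD is block-diagonal by construction; block members share a locus
within the clumping window, everything else is spaced beyond it.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: winner's-curse selection of instruments in
an external discovery GWAS (selection here acts on the same simulated
exposure statistics, which *attenuates* IVW toward the null when the
significance filter is applied; the calibration suite therefore estimates on
the full panel), individual-level genotypes, population structure or sample
overlap, realistic LD beyond uniform blocks, allele-frequency/effect-size
coupling, or liability-scale case-control subtleties beyond the log-odds SE
approximation.

## Benchmark scenarios and problem sizes

The statistical test suite and `scripts/acceptance.py` use these scenarios,
chosen once as the package's reference conditions:

* **Calibration/null** — defaults above, 500 replicates: IVW mean within 3
  Monte-Carlo SEs of ln 0.72, CI coverage in [92.5%, 97.5%], Cochran's Q
  5%-level rejection in [3%, 7%].  (At the default per-instrument strength,
  F&#772; &asymp; 37, the known finite-sample IVW dilution of order 1/F is
  about 2.6% of the effect — real but inside the Monte-Carlo band.)
* **Robustness ordering** — 50 instruments with `total_r2` 0.05, 40%
  invalid with direct effects N(0.1, 0.05), InSIDE holding, 200 replicates.
  Instruments are deliberately strong (F&#772; &asymp; 1100) so estimator
  properties, not instrument noise, drive the comparison — the standard way
  such benchmarks are constructed.  Expected: weighted median beats IVW in
  ≥ 80% of replicates; Egger intercept tracks the realized mean direct
  effect within 3 MC SEs.
* **MR-PRESSO** — 30 instruments: null rejection ≤ 10% over 200 replicates
  at n_sim = 500; one 10&times; outlier detected in ≥ 90% of 100 replicates
  at n_sim = 1000 (n_sim = 500 could never clear the Bonferroni floor at
  J = 30, see above).
* **Reverse null** — defaults plus 17 outcome-specific variants; the
  reverse IVW CI covers 0 in ≥ 90% of 100 replicates.  Reverse instrument
  selection reuses the forward thresholds (p &lt; 5&times;10⁻⁸, same
  clumping), a documented assumption.

## Numerical conventions and degenerate inputs

* 95% CI multiplier fixed at 1.959964; OR-scale bounds are exp of the
  beta-scale bounds exactly.
* Clumping and weighted-median sorts are stable (mergesort) with documented
  tie-breaks; estimates are invariant to record order.
* Wald ratio at &gamma;&#770; = 0 is a domain error; the weighted-median
  bootstrap substitutes the smallest positive float if a resample hits 0.
* IVW needs J ≥ 1 (heterogeneity J ≥ 2), Egger and weighted median J ≥ 3,
  MR-PRESSO J ≥ 4; violations raise typed errors, and a pipeline stage that
  empties the instrument set raises an error naming the stage.
* LD matrices must be symmetric within 10⁻⁸ (then symmetrized as
  (M+M&#7488;)/2) with unit diagonal; entries outside [0,1] are rejected
  naming the offending cell.
* File round-trips preserve floats exactly (shortest round-trip
  representation); validation failures are row-indexed, and strict mode
  (default) refuses to drop data silently.

## Known limitations

No proxy-variant lookup for instruments missing in the outcome; no
Steiger filtering, multivariable or mediation MR; no mode-based or
contamination-mixture estimators; no additive random-effects IVW; no
winner's-curse correction.  The MR-PRESSO null simulation redraws exposure
effects around their estimates, which slightly overdisperses the null and
makes the global test mildly conservative — visible in the acceptance
numbers (rejection a little under the nominal 5%).
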