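# summr

Two-sample Mendelian randomization (MR) from GWAS summary statistics.

Mendelian randomization uses genetic variants as instrumental variables to
estimate the causal effect of an exposure (for example, years of educational
attainment) on an outcome (for example, risk of endometrial cancer), from
summary-level association statistics alone.  Because alleles are randomized
at conception, a valid instrument is immune to the confounding and reverse
causation that plague observational epidemiology.  `summr` is aimed at
epidemiologists and statistical geneticists who want a scriptable, fully
seeded pipeline for this design: instrument selection, harmonization, four
causal estimators, pleiotropy diagnostics, reverse-direction analysis, and a
synthetic summary-statistics generator with known ground truth for validating
every stage.

## The model

For instrument *j*, let &gamma;&#770;<sub>j</sub> (SE
&sigma;<sub>Xj</sub>) be its association with the exposure and
&Gamma;&#770;<sub>j</sub> (SE &sigma;<sub>Yj</sub>) its association with the
outcome, estimated in two non-overlapping samples.  Each instrument gives a
Wald ratio estimate of the causal effect &beta;:

- **Wald ratio** &beta;&#770;<sub>j</sub> = &Gamma;&#770;<sub>j</sub> / &gamma;&#770;<sub>j</sub>, se = &sigma;<sub>Yj</sub>/|&gamma;&#770;<sub>j</sub>|
- **IVW** (the primary estimator): inverse-variance-weighted mean of the
  ratios with weights w<sub>j</sub> = &gamma;&#770;<sub>j</sub>²/&sigma;<sub>Yj</sub>²,
  equal to weighted least squares of &Gamma;&#770; on &gamma;&#770; through
  the origin.  A multiplicative random-effects model inflates the SE by
  max(1, &radic;(Q/(J−2))) where Q = &Sigma; w<sub>j</sub>(&beta;&#770;<sub>j</sub> − &beta;&#770;)²
  is Cochran's heterogeneity statistic (&chi;²<sub>J−1</sub> under homogeneity).
- **MR-Egger**: the same regression with an intercept; the slope is robust to
  directional pleiotropy under the InSIDE assumption and a nonzero intercept
  estimates the average direct (pleiotropic) effect per SNP.
- **Weighted median**: the weight-interpolated median of the ordered ratios;
  consistent while valid instruments carry at least half the weight.
- **MR-PRESSO**: a simulation-based global test on the leave-one-out residual
  sum of squares, with per-SNP outlier detection and an outlier-corrected IVW
  estimate.

Instrument strength is screened with the per-variant explained variance
R² = 2&beta;²p(1−p) / [2&beta;²p(1−p) + 2se²Np(1−p)] and
F = R²(N−2)/(1−R²); F &lt; 10 flags a weak instrument.  Binary-outcome power
and required sample size follow the standard normal approximation with
b = ln(OR), instrument R² and case fraction K.

For a binary outcome all effects are log odds ratios per SD of exposure and
are also reported as ORs with 95% CIs.

## Worked example

Simulate a study-scale dataset (306 instruments, exposure GWAS N = 1,131,881,
binary outcome GWAS N = 121,885 with case fraction 0.106, true causal
OR = 0.72 per SD of exposure) and run the forward pipeline:

```python
import summr
from summr.pipeline import AnalysisConfig, OutcomeSpec, render_report, run_forward

model = summr.SimulationModel(seed=42)          # true OR = 0.72 per SD
exposure, outcome, ld, truth = summr.simulate_two_sample(model)
config = AnalysisConfig(
    seed=7,
    outcomes=[OutcomeSpec(name="disease", trait_type="binary",
                          case_fraction=12906 / 121885)])
report = run_forward(config, exposure=exposure,
                     outcomes={"disease": outcome}, ld=ld)
render_report(report, "results/example")
```

`results/example/summary.md` then contains (byte-identical on every run with
this config and seed):

```
| Method | SNPs | OR (95% CI) | p |
|---|---|---|---|
| IVW | 109 | 0.88 (0.72–1.08) | 0.208 |
| Weighted median | 109 | 0.93 (0.68–1.27) | 0.628 |
| MR-PRESSO (outlier-corrected) | 109 | 0.88 (0.72–1.08) | 0.208 |
| MR-Egger | 109 | 1.01 (0.58–1.79) | 0.961 |

- Cochran's Q = 110.95 (df = 108, p = 0.404)
- MR-Egger intercept = -0.002147 (p = 0.592)
- MR-PRESSO global test p = 0.417 (0 outlier(s))
- Weak instruments (F < 10): 0 (min F = 29.9; summed R² = 0.008396)
- Leave-one-out: 0 influential drop(s) flagged
```

Reading the output: 109 of the 306 simulated variants pass genome-wide
significance (p &lt; 5&times;10⁻⁸) in this realization and survive clumping
and harmonization; every one is a strong instrument (min F = 29.9).  The four
estimators agree in direction, heterogeneity and pleiotropy diagnostics are
null, and no single variant drives the result.  The IVW OR (0.88) sits
between the generating OR (0.72) and the null: selecting instruments by
significance in the same exposure GWAS that supplies their effect sizes
inflates the selected |&gamma;&#770;| (winner's curse) and attenuates the
ratio estimates — visible here because the ground truth is known.  Estimating
on the full simulated panel without selection (`summr.harmonize` +
`summr.ivw` directly) recovers OR &approx; 0.72 on average.

The same pipeline is scriptable from a shell (`summr simulate`,
`summr harmonize`, `summr mr`, `summr reverse`, `summr report`); see
`summr --help`.

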