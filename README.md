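# batrasch

Rasch construct validation for the **Burnout Assessment Tool (BAT)** — a
23-item burnout questionnaire with four subscales (exhaustion EX, mental
distance MD, cognitive impairment CI, emotional impairment EI; items scored
1–5 by frequency). The package implements the full partial-credit-model
workflow a psychometrician runs to decide whether the 23 item responses can
be combined into a single burnout score:

1. **Item-level analysis** — fit the partial credit model (PCM)

   *P(X<sub>i</sub> = x | θ) ∝ exp(xθ − Σ<sub>k≤x</sub> δ<sub>ik</sub>)*

   by conditional maximum likelihood (CML; person-distribution-free), then
   check item fit residuals (±2.5), class-interval item χ² (Bonferroni at
   α = 0.01), threshold ordering (with the hybrid ordered/disordered/
   undecided hypothesis test on reversed pairs), local dependency
   (residual correlations more than 0.2 above the average), Smith's PCA/
   t-test of unidimensionality (binomial 95% CI on the proportion of
   |t| > 1.96), DIF by age group (two-way ANOVA of standardized residuals,
   uniform and non-uniform), PSI reliability and targeting.
2. **Testlet analysis** — sum each subscale into one polytomous super-item,
   re-fit, and decompose total variance via the two alpha coefficients:
   non-error = α<sub>items</sub>, common true score = α<sub>testlets</sub>,
   plus the common/non-error ratio and the average disattenuated latent
   correlation between subscales.
3. **Scoring & descriptives** — BAT total and subscale means on the 1–5
   scale, medians/quartiles by median-age split with Mann–Whitney tests.

Because real survey data of this kind are rarely shareable, the package
ships a **synthetic-data generator** (`batrasch.synthetic_data`) whose
defaults reproduce the published Swedish calibration of the BAT: the 23×4
item thresholds, person locations N(−0.95, 0.63) on the logit scale,
optional between-subscale latent correlation, pairwise response-dependency
injection and uniform/non-uniform DIF injection. Every diagnostic in the
pipeline is exercised against this generator in the test suite.

## Worked example

Simulate a cohort of 800 respondents whose four subscales correlate 0.6 at
the latent level (burnout as four inter-related symptoms), then run the
two-step validation:

```python
from batrasch import default_bat_config, uniform_offdiag_corr, generate, run_pipeline

cfg = default_bat_config(n_persons=800, seed=1)
cfg.latent_corr = uniform_offdiag_corr(cfg.spec, 0.6)
rm = generate(cfg)
result = run_pipeline(rm=rm, outdir="report", seed=1)
print(result["summary"]["item_level"])
print(result["summary"]["testlet_level"])
print(result["summary"]["variance_decomposition"])
```

Output (abridged from `report/summary.json`):

```text
item_level:    psi 0.75  alpha 0.74  smith_pct 9.50  ci (7.56, 11.75)  unidimensional False
testlet_level: psi 0.66  alpha 0.62  smith_pct 5.26  ci (3.82, 7.05)   unidimensional True
variance_decomposition: nonerror 0.743  common 0.622  unique 0.121  error 0.257
                        common_over_nonerror 0.837
average_disattenuated_latent_correlation 0.6011
```

Reading: at item level Smith's test rejects unidimensionality (9.5% of
person t-tests significant, CI lower bound above 5%), because the four
subscales share only part of their variance. Re-analysed as four testlets
the scale fits (5.3%, CI lower bound below 5%), 84% of the systematic
variance is common to all subscales, and the average disattenuated
correlation recovers the generating 0.6 — the justification for reporting
one total burnout score. PSI and alpha both drop from item to testlet
level, as expected when local dependency is absorbed.

The same pipeline runs on a respondent CSV (columns EX1..EX8, MD1..MD5,
CI1..CI5, EI1..EI5 coded 1–5, optional `age`):

```bash
batrasch validate responses.csv --outdir report --sample-size 800
batrasch simulate --n 800 --seed 1 --latent-corr 0.6 --out sim.csv
batrasch fit sim.csv --outdir fit
batrasch score sim.csv --out scores.csv
```

## Layout

| module | contents |
| --- | --- |
| `data_model` | scale spec, CSV I/O, complete-case filter, random splits |
| `synthetic_data` | PCM generator: thresholds, latent structure, DIF, dependency |
| `pcm_core` | PCM probabilities, ESF recursions, CML items, ML persons |
| `fit_diagnostics` | residuals, fit residuals, item χ², threshold ordering |
| `dimensionality` | residual correlations, PCA, Smith's test |
| `dif_analysis` | two-way ANOVA of residuals (uniform / non-uniform DIF) |
| `testlet_analysis` | testlets, alpha, PSI, variance decomposition, latent r |
| `reporting` | burnout scores, descriptives, targeting, pipeline runner |

See `docs/methods.md` for the statistical details and design choices.
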