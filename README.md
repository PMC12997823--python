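# rsfkit

Multi-scale resource-selection analysis for GPS-tracked, home-range
holding animals — built around the "landscape of fear" question: how
does a prey species balance forage acquisition against predation and
human risk, in space (inside vs outside a protected core), over the
day, and over the lunar cycle?

The package implements the full analysis chain used in
telemetry-based habitat-selection studies of ungulates:

* **Covariate grids** — percent woody cover (WC), terrain ruggedness
  (TRI), focal Shannon vegetation diversity (SVD), proximity to
  rivers/drainages (ProxW) and seasonal NDVI on a common 30 m grid,
  with an ESRI ASCII-grid reader/writer and daily moon-illumination
  series.
* **Two-level use–availability sampling** — landscape (2nd order:
  home-range placement) and home-range (3rd order: within-range use)
  designs at a 1:10 use:available ratio, plus 24 hourly split designs.
* **Binomial mixed models** — a native Laplace GLMM fitter (penalized
  IRLS + bounded quasi-Newton over variance components) with crossed
  and nested random intercepts (management area, individual, year,
  season-within-year), cross-checked against plain logistic regression
  and an adaptive Gauss–Hermite oracle.
* **Hypothesis-set inference** — the 13 forage/risk/trade-off ×
  generic/spatial/temporal/spatio-temporal model structures, AIC
  ranking, and the ΔAIC-ratio set-support statistic.
* **Validation** — Boyce-style k-fold cross-validation via Spearman
  correlation of RSF bin ranks with area-adjusted frequencies.
* **Temporal analyses** — hourly split models, single (noon–midnight)
  and double (dawn–dusk) raised-cosine regressions of hourly
  coefficients, and covariate × moon interaction curves.
* **Functional responses** — Pearson correlation between landscape- and
  home-range-level selection ratios across individuals.
* **A synthetic world** — spatially autocorrelated landscapes and
  GPS-like tracks simulated from known selection coefficients, so the
  entire pipeline is validated by parameter recovery.

The model at the core is a use–availability RSF: for covariates
x standardized per SD,

    w(x) = exp(β·x + (δ·x)·InOut + (γ·x)·Moon)

fitted as a binomial-logit GLMM with random intercepts, where InOut
marks locations outside the strictly protected core and Moon is percent
lunar illumination / 100. Set support is summarized by the ΔAIC-ratio:
mean ΔAIC over all hypothesis models divided by mean ΔAIC within the
named set (null model excluded; > 1 ⇒ above-average support).

## Worked example: support ratios from a published AIC table

The package bundles the model-parsimony table of a published impala
telemetry study in the Serengeti ecosystem (36 collared females,
211,767 hourly relocations) as an example dataset:

```python
>>> from rsfkit.datasets import published_aic_table
>>> from rsfkit.model_selection import all_set_ratios, compare_from_aic
>>> comp = compare_from_aic(published_aic_table("homerange"), "homerange")
>>> comp.best
'Sfr'
>>> {k: round(v, 2) for k, v in all_set_ratios(published_aic_table("homerange")["dAIC"]).items()}
{'G': 0.78, 'S': 1.4, 'T': 0.78, 'ST': 1.38, 'f': 1.35, 'r': 0.52, 'fr': 3.06}
```

The best-supported structure is `Sfr` — the spatially adjusted
trade-off between forage availability and risk exposure — and the
trade-off set (`fr`, ratio 3.06) carries roughly three times the
average support, while risk-only structures (`r`, 0.52) fall below
average: within their home ranges these animals balance forage and
risk, adjusted to whether they are inside or outside the protected
core.

The same arithmetic is available from the shell:

```bash
rsfkit compare --level homerange --published
```

## Running the pipeline on a synthetic world

```bash
rsfkit run-all --seed 7 --out demo_out
```

simulates a landscape and eight tracked individuals, builds both
use–availability designs, fits all candidate structures, and writes the
comparison tables, cross-validation summaries, diel tests and
functional-response correlations plus a manifest of seeds and counts to
`demo_out/`. With seed 7 the command prints:

```
landscape: best model Sfr; ratios {'G': 0.78, 'S': 1.39, 'f': 1.06, 'r': 0.6, 'fr': 2.65}
homerange: best model Sfr; ratios {'G': 1.05, 'S': 1.28, 'T': 0.83, 'ST': 0.95, 'f': 0.9, 'r': 0.66, 'fr': 2.69}
```

— the generating spatial trade-off structure (`Sfr`) is identified at
both levels, and the trade-off set carries the strongest support, as it
should under the simulator's default landscape-of-fear truth. Every
stage takes an explicit seed; re-running with the same configuration
reproduces identical outputs.

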