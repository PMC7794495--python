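# owlfam

Analytical machinery for studying **family living through delayed natal
dispersal** in burrowing owls (*Athene cunicularia*), built as a tested
pipeline on synthetic data. In this system a small fraction of
first-year birds stay at their natal nest through the next breeding
season, producing "family units" — a breeding pair plus one or two
extra adults — more often in urban (≈7% of breeding events) than in
rural (≈3%) habitat. The package is for quantitative ecologists who
want the full statistical chain behind such a study in one place:

- **`synthetic_data`** — a seeded individual-based simulator of the
  whole system: clustered nest landscapes, annual breeding events with
  family-unit occurrence and zero-inflated productivity, chick
  morphometrics, monthly natal-nest attendance, multi-year encounter
  histories, dispersal distances, and microsatellite genotypes down
  family pedigrees.
- **`metrics`** — the spatial conspecific covariates: the aggregation
  index *S*ᵢ = Σⱼ≠ᵢ exp(−dᵢⱼ) (distances in km), its
  productivity-weighted variant, the conspecific-productivity residual,
  and body condition as the residual of log₁₀(mass) on
  1.45 + 0.37·log₁₀(wing).
- **`model_selection`** — GLM/GLMM fitting (binomial, Poisson,
  negative binomial, Gaussian; intercept-only zero inflation; one or a
  crossed pair of random intercepts by Laplace-approximated marginal
  ML) plus the AICc stack: AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), ΔAICc,
  Akaike weights w = exp(−Δ/2)/Σexp(−Δ/2), and full-model averaging
  with unconditional CIs.
- **`cmr`** — a Cormack–Jolly–Seber engine with two age classes
  (juvenile survival over the first interval after marking, adult
  thereafter), habitat groups, additive time effects, family-unit and
  body-condition covariates on survival, effort/habitat/time on
  recapture, m-arrays, model averaging and bootstrap goodness of fit.
- **`resampling`** — the dispersal-distance permutation test (group
  median against medians of pool subsamples, p = count(null ≤ obs)/n)
  and the 200-dataset resampled survival comparison with a one-tailed
  Z-test.
- **`kinship`** — ML relatedness classification over U/HS/FS/PO via
  identity-by-descent coefficient mixtures, Cervus-style parentage LOD
  scores (pair and trio), and simulation-calibrated confidence
  thresholds, with a per-allele substitution error model.
- **`pipeline`** — the named analyses end to end, each with its
  candidate model set hard-coded to match the corresponding published
  table, plus a thin `owlfam` command-line interface.

See `docs/methods.md` for the models, assumptions, defaults and
numerical choices.

## Worked example

Simulate ten breeding seasons on a 200-nest landscape, fit the
family-unit occurrence model set, and recover survival from encounter
histories:

```python
import pandas as pd
from owlfam import SimulationConfig, synthetic_data as sd, pipeline
from owlfam.cmr import CJSDesign, fit_cjs

cfg = SimulationConfig(seed=7, n_nests_urban=100, n_nests_rural=100,
                       n_years=10)
nests = sd.simulate_landscape(cfg)
events = sd.simulate_breeding_seasons(nests, cfg)

rep = pipeline.run_family_unit_analysis(events)
print(rep.model_table.head(4))
print(rep.averaged)

chicks = pd.DataFrame({"chick_id": [f"c{i}" for i in range(2000)],
                       "habitat": ["urban"] * 1000 + ["rural"] * 1000})
histories = sd.simulate_encounter_histories(chicks, cfg, n_occasions=10)
fit = fit_cjs(histories, CJSDesign(name="(JuvU/JuvR/Ad)"))
for a in ("JuvU", "JuvR", "Ad"):
    est, lo, hi = fit.survival(a)
    print(f"phi_{a}: {est:.3f} (95% CI {lo:.3f}-{hi:.3f})")
```

Output:

```
                           model  k   aicc  delta  weight
                         density  3 761.81   0.00    0.50
               habitat + density  4 763.77   1.95    0.19
habitat + productivity + density  5 764.95   3.14    0.10
                 habitat*density  5 764.98   3.16    0.10
        term  estimate  ci_low  ci_high
       urban     0.065  -0.595    0.724
        dens     0.565   0.148    0.983
      presid     0.013  -0.155    0.181
...
phi_JuvU: 0.272 (95% CI 0.241-0.306)
phi_JuvR: 0.222 (95% CI 0.193-0.253)
phi_Ad: 0.729 (95% CI 0.695-0.760)
```

Models containing conspecific density dominate the set and its
model-averaged log-odds slope (0.57 per SD of the aggregation index)
excludes zero, recovering the generating density effect; the null model
sits ~30 AICc units back. The CJS fit recovers the generating survival
probabilities (urban juveniles 0.29, rural juveniles 0.21, adults 0.71)
within sampling error, with recapture estimated jointly.

The same machinery is available from a shell:

```bash
owlfam simulate --seed 7 --out run/
owlfam families --events run/events.csv --out run/family_report
owlfam cmr --inp run/encounters.inp --out run/survival_report
owlfam permtest --delayed delayed.csv --pool pool.csv --iters 1000 --seed 1
```

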