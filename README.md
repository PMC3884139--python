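# panelmsm

Continuous-time multi-state models for intermittently observed (panel)
longitudinal data, with first-class support for unobservable and partially
observed states:

* **model_core** — declarative model specification: state graphs, constant /
  piecewise-constant / Weibull proportional intensities, parameter sharing,
  equality constraints, and derived-baseline rules (ratio-product and
  exponential-offset re-parameterizations).
* **panel_likelihood** — interval-censored likelihoods via products of matrix
  exponentials, exact-time event contributions, censoring sets, state
  occupancy, and expected length of stay.
* **hidden_states** — misclassification (hidden Markov) models; the remission
  workflow that recodes zero-count runs into observed codes O1/O2/O3, fits
  the hidden three-state model (Model A) or the two-state recodings (Models
  B/C), and reports Bayes posteriors for misclassified visits.
* **semicompeting** — the five-state semi-competing-risks model with an
  unobservable post-loss-to-follow-up event state, a fixed sensitivity
  constant `k`, Weibull intensities, and cumulative incidence of the first
  event.
* **expanded_joint** — joint modelling of an ordinal outcome and a rapidly
  fluctuating ordinal covariate on an expanded lattice state space, with the
  constraint system that makes it correspond to a proportional-intensity
  model, plus the carried-forward "misspecified" comparator.
* **clustered_frailty** — clustered progressive four-state damage processes
  sharing a unit-mean gamma random effect, marginalized by tilted
  Gauss–Laguerre quadrature; symmetry offsets with Wald intervals.
* **simulate** — seeded exact-path simulation (cumulative-hazard inversion)
  and panel observation for every model class; a scenario library mirrors
  each application's observation scheme.
* **inference** — quasi-Newton maximum likelihood, numerical-Hessian
  covariances, likelihood-ratio tests, Wald summaries.
* **io / cli** — panel CSV dialect, model-configuration JSON, run manifests,
  and the `panelmsm` command-line tool.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the long-running acceptance criteria
(oracle equivalences, closed-form limits, structural constraint checks,
seeded parameter-recovery studies, directional findings, worked examples);
the remaining files are fast unit/property tests.

## CLI

```sh
# simulate a seeded scenario to the panel CSV dialect
panelmsm simulate --scenario remission --n 200 --seed 7 --out data.csv

# fit a model described by a JSON config
panelmsm fit --config model.json --data data.csv --out fit.json

# predictions from a fitted model
panelmsm predict --config model.json --fit fit.json --quantity los --horizon 40 --out los.csv

# count-recoding remission workflow (Models A/B/C)
panelmsm remission --counts-csv counts.csv --model A --report posterior --out post.csv
```

Every run writes a `<out>.manifest.json` with config/data hashes, the seed
and the package version.  Exit codes: 0 ok, 1 user error, 2 numerical
failure.

### Panel CSV dialect

Columns: `subject`, optional `cluster`/`unit`/`entry`, `time`, `state` (a
state label, a comma-joined censoring set, or `*` for fully unknown),
`exact` (0/1 — exactly observed transition time), remaining columns are
covariates carried forward to the next visit.  Round trips are exact.

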