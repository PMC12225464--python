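# patroldetect

Bayesian analysis of enforcement-patrol records that separates two confounded
processes: how often violations occur, and how good patrols are at detecting
them.

Enforcement agencies routinely log every patrol action — where it happened,
who it targeted, how long it took — together with a single binary outcome:
was a violation found or not. That outcome conflates two things. A patrol may
come back empty because no violation was present, or because one was present
and missed. `patroldetect` models the two stages explicitly, for datasets
shaped like fisheries supply-chain enforcement records (regions, supply-chain
actor types from fishers to restaurants, species groups, violation types,
patrol time and group size).

## The model

For patrol *i* with binary outcome *y<sub>i</sub>*:

```
y_i ~ Bernoulli(P_i)          P_i = p_i · s_i          s_i ~ Bernoulli(v_i)

logit(p_i) = μ_p + b₁·T_i + b₂·N_i + b₃[R_i] + b₄[A_i] + b₅[Y_i]
logit(v_i) = μ_v + b₆[V_i] + b₇[S_i]
```

*v<sub>i</sub>* is the probability that a violation is present in the context
of the patrol (driven by violation type V and species group S);
*p<sub>i</sub>* is the **detectability** — the probability of detecting the
violation given that it is present (driven by patrol time T and group size N,
both min-max scaled to [0, 1], and by actor A, region R and year Y).
Marginalising the latent indicator *s<sub>i</sub>* gives
P(y=1) = v·p, which the sampler uses directly.

All coefficients take flat priors on [−2.2, 2.2] (odds ratios of roughly
−90% to +90%), with treatment coding: each factor's reference level is fixed
at 0 and every other level is a log-odds ratio against it. Inference is by
adaptive random-walk Metropolis (3 chains × 600 warmup + 2400 sampling by
default), checked with split-chain Gelman–Rubin R̂ (< 1.1) and compared across
predictor assignments with WAIC. Because detected violations are a small
minority of patrols, classification uses an F1-optimal threshold found by a
grid sweep rather than the default 0.5.

## Worked example

```python
import patroldetect as pdt

config = pdt.reference_config(seed=42, n_records=5000, n_regions=4, n_actors=4,
                              n_species=6, n_violations=3)
frame, truth = pdt.simulate_records(config)

clf = pdt.ConditionalDetectionClassifier(scheme=config.scheme,
                                         tune_threshold=True, random_state=0)
clf.fit(frame)
print(clf.rhat_report_.max_rhat, clf.threshold_)
print(clf.headline_summary())
print(clf.summarize_factor(frame, "actor"))
```

prints (abridged):

```
simulated 5000 patrols, detected fraction 0.189
max split-Rhat: 1.018 (pass=True)
WAIC: 3912.7
F1-optimal threshold: 0.20 (best F1 = 0.511)
mean detectability p: 0.429 (SD 0.295)
mean violation probability v: 0.446 (SD 0.220)
mean overall probability v*p: 0.190 (SD 0.172)
factor              level   mean     lo     hi  effort_share  is_reference
 actor Small-scale fisher  0.000  0.000  0.000         0.332          True
 actor  Industrial fisher  0.559  0.247  0.882         0.269         False
 actor        Transporter -1.654 -2.062 -1.277         0.224         False
 actor          Processor  1.790  1.381  2.157         0.176         False
```

The synthetic dataset was generated from known coefficients, so the fit can
be read against the truth: the true actor effects were +0.87 (Industrial
fisher), −1.79 (Transporter) and +2.09 (Processor), each inside its 95%
credible interval above. The headline block is the across-patrol mean (and
SD) of the posterior-mean detectability *p*, violation probability *v* and
their product — the unconditional chance a patrol records a violation. The
F1-optimal threshold (0.20 here) sits well below 0.5 because detections are
the minority class. `effort_share` is the proportion of patrols aimed at each
category, the quantity to hold against detectability when asking whether
effort is well targeted.

The same pipeline is scriptable:

```bash
patroldetect simulate --seed 5 --n-records 10000 --out patrols.csv
patroldetect fit --data patrols.csv --out runs/fit
patroldetect evaluate --data patrols.csv --fit-dir runs/fit --out runs/eval
patroldetect report --data patrols.csv --fit-dir runs/fit --out runs/report
```

## Layout

| module | contents |
| --- | --- |
| `patroldetect.records` | record data model, CSV I/O, category schemes and collapsing, min-max scaling, collinearity screen, design matrices |
| `patroldetect.synthetic` | ground-truth generator executing the two-stage process |
| `patroldetect.model` | logit submodels, marginalised likelihood, box prior, log posterior |
| `patroldetect.sampling` | adaptive Metropolis sampler, split-R̂, ESS, WAIC, model ladder |
| `patroldetect.evaluation` | posterior-predictive probabilities, confusion matrix, F1 threshold sweep |
| `patroldetect.reporting` | category log-odds summaries with effort shares, annual detectability series, headline probabilities |
| `patroldetect.estimator` | `ConditionalDetectionClassifier`, the scikit-learn-style front end |
| `patroldetect.cli` | `patroldetect simulate / fit / evaluate / report` |

See `docs/methods.md` for modelling assumptions, numerical choices and known
limitations.
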