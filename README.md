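# bullynet

Tree-structured Bayesian networks for questionnaire-based screening of
**bullying risk** and **help-seeking behavior** in school children.

School bullying is hard to detect: both perpetrators and victims tend to stay
silent, and the strongest individual predictors — temperament traits and
family-functioning features — are measured on psychometric subscales rather
than observed directly. `bullynet` provides a compact, fully reproducible
pipeline for the kind of analysis school psychologists and researchers run on
such data: given a cohort with EAS temperament subscales (Distress, Fear,
Anger, Activity, Sociability, Emotionality), FACES IV-SOR family subscales
(Balanced Cohesion, Balanced Flexibility, Family Communication, Family Life
Satisfaction) and binary bullying / help-seeking flags, it

1. compares outcome groups per subscale (means, SDs, Mann–Whitney *U*),
2. binarizes each subscale at a screening cut-point (e.g. Distress > 12.5),
3. learns a tree-shaped Bayesian network with the **Chow–Liu algorithm**
   (maximum-weight spanning tree over plug-in mutual information),
4. fits one conditional probability table (CPT) per node by
   maximum-likelihood (optionally Laplace-smoothed) frequencies, and
5. answers prior and posterior queries — e.g. P(bullying | full high-risk
   score profile) — by exact sum-product message passing on the tree.

Because cohorts of this kind are rarely shareable, the package includes a
first-class synthetic-cohort generator calibrated to published group
descriptives (n = 75, 18 bullies, 72 help-seekers), plus a "designed" mode
with analytically known likelihood ratios for method validation.

## The model

For discretized variables $X_1,\dots,X_k$ and an outcome $H$, the Chow–Liu
procedure selects the spanning tree $T$ maximizing $\sum_{(i,j)\in T}
\hat I(X_i; X_j)$, where $\hat I$ is the maximum-likelihood mutual information
$\sum_{x,y}\hat p(x,y)\log\frac{\hat p(x,y)}{\hat p(x)\hat p(y)}$. Edges are
oriented away from the outcome node and the joint factorizes as
$P(H)\prod_c P(X_c \mid X_{\mathrm{pa}(c)})$. Evidence
$E = \{X_i = e_i\}$ is propagated exactly; with conditionally independent
predictors this reduces to the familiar odds product

$$\frac{P(H\mid E)}{P(\bar H\mid E)} = \frac{P(H)}{P(\bar H)}
\prod_i \frac{P(e_i \mid H)}{P(e_i \mid \bar H)}.$$

Predictors are the outcome's tree neighbors that pass a G-test
($G = 2n\hat I$, $\chi^2$ with 1 df for binary pairs).

## Worked example

Simulate a designed cohort of 5,000 students in which the six bullying-screen
subscales each favor their risk-side state with probability 0.95 given a
bully and 0.2 otherwise (prevalence 0.24), then learn and query the network:

```python
from bullynet import (CohortConfig, DesignedSignal, PipelineConfig,
                      default_bullying_scheme, run_pipeline)

scheme = default_bullying_scheme()
config = PipelineConfig(cohort=CohortConfig(
    n=5000, prevalence_bullying=0.24, mode="designed",
    designed_outcome="bullying",
    designed_signal={v: DesignedSignal(0.95, 0.2) for v in scheme.variables},
    seed=1))
model = run_pipeline(config).models["bullying"]
print(sorted(model.predictors))
print(model.prior["yes"], model.posterior_high["yes"], model.posterior_low["yes"])
```

prints

```
['eas_activity', 'eas_distress', 'eas_fear', 'eas_sociability',
 'sor_balanced_cohesion', 'sor_balanced_flexibility']
0.2406 0.999735820028579 1.180184530424609e-08
```

All six predictors attach directly to the outcome (the learned tree is a
star, as conditional independence given the class implies), the fitted prior
matches the simulated prevalence, and the posterior probability of bullying
is ≈ 0.9997 for a student showing the complete high-risk profile (Distress,
Fear, Activity, Sociability elevated; Balanced Cohesion and Flexibility low)
versus ≈ 10⁻⁸ for the complementary low-risk profile — the 99% / 1% screening
extremes, here with likelihood ratios large enough to push far past them.

The same analysis runs from a shell:

```bash
bullynet simulate --n 75 --seed 4 --out cohort.csv
bullynet analyze --cohort cohort.csv --out-dir results/
bullynet query --network results/network_bullying.json \
    --query bullying --evidence eas_distress=high --evidence eas_fear=high
```

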