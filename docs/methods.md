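# Methods

## Scope and data model

`bullynet` analyzes cohorts of school-aged students described by ten
questionnaire subscales and two binary outcome flags. The EAS temperament
instrument contributes five primary subscales (Distress, Fear, Anger,
Activity, Sociability), each the sum of four 1–5 Likert items, hence integer
scores in [4, 20], and a composite Emotionality = Distress + Fear + Anger in
[12, 60]. The FACES IV-SOR family instrument contributes Balanced Cohesion
and Balanced Flexibility (7 items, [7, 35]) and Family Communication and
Family Life Satisfaction (10 items, [10, 50]). Outcomes are self-reported
bullying (intimidating/damaging/threatening behavior at least twice in
recent months) and help-seeking (declaring people who can be asked for help).
Ranges are configurable; the defaults follow the instruments' item counts.

## Synthetic cohorts

No real cohort ships with the package; the generator is first-class,
tested code that produces cohorts with the statistical structure the
analysis assumes.

**Tabled mode** draws each primary subscale from a normal distribution
conditional on one outcome group, rounds to the nearest integer and clips to
the instrument range. Default group means/SDs are the published descriptives
for bullies (n = 18) vs non-bullies (n = 57); an alternative parameter set
conditions on help-seeking (72 vs 3). A single cohort can only be calibrated
to one grouping at a time (`tabled_outcome`); the other flag is drawn
independently at its prevalence (default 0.24 bullying, 0.96 help-seeking).
Outcome flags are Bernoulli by default; `exact_prevalence=True` pins the
counts (e.g. exactly 18/75), which is what the default pipeline uses since
those are observed study counts, making the fitted priors exactly 0.24
and 0.96.

*Calibration.* Rounding inflates variance (≈ +1/12) and clipping at the
range boundary biases both moments — for the wide 10–50 scales (means
≈ 37–39, SD ≈ 9) the censoring bias on the mean is ≈ 0.3–0.5, far from
negligible. The generator therefore solves, per (variable, group), for the
latent normal (μ, σ) whose *rounded-and-clipped integer distribution* has
exactly the target mean and SD (two-dimensional moment inversion via
`scipy.optimize.root`; results cached). A convergence test at n = 400,000 —
sized so that 3·SE < 0.1 for the widest scale — confirms every per-group
sample mean and SD lands within 0.1 of its target.

Emotionality is computed as the sum of its three components, matching the
instrument (and the published bully-group means: 11.28 + 9.89 + 11.55 =
32.72). Under within-group independence of the components the composite SD
is √(3.10² + 3.41² + 3.55²) ≈ 5.82, smaller than the published 7.59; the
discrepancy implies positive within-group correlation among components in
real data. The published tables report no correlations, so none are imposed;
only the composite's mean, not its SD, is a calibration target. More
generally, tabled mode assumes subscales are conditionally independent given
the outcome class — real questionnaire data are not, so passing tests
demonstrate correct mechanics, not real-world predictive validity.

**Designed mode** gives each signal variable a class-conditional probability
of its *pattern state* — the state it takes in the outcome-favoring evidence
profile (for Cohesion/Flexibility that is "low") — and places an integer
score uniformly on the matching side of the variable's cut-point. Non-signal
subscales are uniform over their range, independent of class. This yields
analytically known likelihood ratios: with pattern probabilities 0.95 vs
0.2 per variable, LR = 4.75 per high-risk observation and 0.05/0.8 = 0.0625
per low-risk one, so the six-variable bullying screen gives posterior odds
(0.24/0.76)·4.75⁶ ⇒ P ≈ 0.9997 and (0.24/0.76)·0.0625⁶ ⇒ P ≈ 2·10⁻⁸ — the
basis for the posterior-extreme validation bounds (≥ 0.99 and ≤ 0.01).
Emotionality is deliberately generated as an independent class-null variable
in this mode (the composite identity is broken) so that structure-recovery
experiments have genuine null EAS variables.

Demographics (sex, age) follow the study-group composition and are generated
independently of outcomes; no model stage uses them.

## Discretization

Each modeled subscale is binarized at a cut-point with a per-rule boundary
convention, because the published screening profile mixes strict and
non-strict wording across variables. Defaults encode that wording literally:

| variable | cut | convention | high-risk state |
|---|---|---|---|
| EAS Distress | 12.5 | > | high |
| EAS Fear | 9 | > | high |
| EAS Activity | 12.5 | > | high |
| EAS Sociability | 9 | > | high |
| SOR Balanced Cohesion | 34.5 | > | low |
| SOR Balanced Flexibility | 27.5 | > | low |

Help-seeking screen: Family Satisfaction > 12, Family Communication ≥ 22.5
(non-strict), Sociability > 12.5; the favorable profile is all-high.
Records with missing modeled values are dropped listwise with a logged
count, mirroring the study's exclusion of incomplete questionnaires.

`learn_cut_point` reconstructs a plausible supervised origin for such
thresholds: among midpoints of adjacent observed scores it picks the one
maximizing mutual information between the binarized score and the outcome,
breaking ties toward the smaller cut. The original thresholds' provenance is
unstated, so this is offered as a reconstruction, not asserted as the
authors' method.

## Structure learning

Pairwise mutual information is the maximum-likelihood plug-in estimate, in
nats, with 0·log(0/q) ≡ 0; terms are summed in sorted order so MI(X,Y) =
MI(Y,X) holds exactly in floating point. The Chow–Liu tree is the
maximum-weight spanning tree via Kruskal on the complete MI graph; equal
weights are consumed in lexicographic order of the sorted variable-name
pair, making the learned structure deterministic across runs and platforms.
The tree is invariant to the MI log base (monotone rescaling), which a test
verifies by re-running in bits.

The tree is rooted at the outcome variable. Orientation does not change the
represented joint — re-rooting and refitting reproduces every posterior to
1e-10 (tested) — but rooting at the outcome yields an interpretable star
when predictors are conditionally independent given the class.

`identify_predictors` filters the outcome's tree neighbors with a G-test:
G = 2n·Î against χ² with (r−1)(c−1) df, default α = 0.01. Raw adjacency
would include noise attachments (every node must attach somewhere); the
filter keeps the false-positive rate at the α level, verified by simulation
under the null.

## CPT estimation and inference

CPT entries are (count + α)/(row_total + α·k) with α = 0 (pure relative
frequencies) by default; a parent state never observed under α = 0 yields a
uniform row with a logged warning. Posteriors are computed by sum-product
message passing over the undirected tree with the CPTs as edge factors and
evidence as indicator potentials — exact inference, verified against
brute-force enumeration of the factored joint on 100 seeded random networks
of up to 12 binary nodes (agreement within 1e-10). Evidence with zero
probability under the model raises `ImpossibleEvidenceError` naming the
assignment: a screening tool should fail loudly, not emit NaN. At the study
size (n = 75) the full published evidence patterns can genuinely have zero
fitted probability under unsmoothed CPTs; the pipeline reports such a
posterior as undefined rather than smoothing silently (set `alpha_laplace`
to smooth deliberately).

Probabilities are reported to 4 decimals in rendered reports; full precision
is retained internally and in JSON serializations, which round-trip exactly.

## Group comparisons

`compare_groups` reproduces the descriptive stage: per-subscale group means
and SDs plus a two-sided Mann–Whitney test, with U reported as
min(U_A, U_B). The p-value is exact when n₁·n₂ ≤ 400 and the pooled sample
is tie-free (exact enumeration under ties is combinatorially infeasible);
otherwise the normal approximation with tie and continuity corrections is
used — integer subscale data nearly always tie, so the asymptotic route is
the norm. Whether published U values used the min convention or a fixed
group's statistic cannot be determined; min is chosen and documented. No
multiple-testing correction is applied, matching descriptive-table practice.

## Problem sizes

Validation simulations use n = 5,000 designed cohorts (posterior extremes),
n = 2,000 for predictor recovery, n = 400,000 for generator calibration
convergence, and ≤ 120 replicates for null-rate checks; each choice is the
smallest size at which the checked property is statistically guaranteed
rather than seed-dependent.

## Known limitations

- The original 75-student dataset is not available; all quantitative checks
  are against arithmetic consequences of published counts and against
  designed simulations, not against the original fitted networks.
- Tree-shaped structures only; no general DAG search, no approximate or
  continuous-variable inference, no multi-bin discretization.
- Tabled cohorts ignore within-group inter-subscale correlations (none are
  published), so structure learned from tabled data reflects marginal group
  separations only.
- This is a methods package: nothing here validates the instruments or the
  screening thresholds for clinical decision-making.
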