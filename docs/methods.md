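# Methods

## The model

`synrisk` quantifies how the joint effect of categorical risk factors on an
outcome deviates from the additive, no-interaction prediction. The inputs are
either a discrete Bayesian network — a DAG over categorical variables
$X_1,\dots,X_n$ with one conditional probability table (CPT) per node, whose
joint distribution factorizes by the chain rule

$$P(x_1,\dots,x_n)=\prod_i P(x_i \mid \mathrm{parents}(x_i))$$

— or a *risk table* that maps factor configurations directly to outcome risk
values on any consistent nonnegative scale.

A **scenario** names an outcome variable and level (e.g. `severity = fatal`),
at least two risk factors each with a *reference* level (the normal state)
and a *risk* level (the exposure), and optional context evidence held fixed
in every query. The *baseline* is the outcome risk with every factor at its
reference level. From the baseline, three deltas are formed:

* single-factor delta $\Delta_i$: risk with factor $i$ at its risk level
  (all others at reference) minus baseline; may be negative (protective);
* additive delta $\sum_i \Delta_i$: the linear no-interaction prediction;
* combined delta $\Delta_{1..n}$: risk with all factors simultaneously at
  their risk levels, minus baseline.

The **nonlinear effect factor** is their ratio,

$$\gamma = \frac{\Delta_{1..n}}{\sum_i \Delta_i},$$

with $\gamma > 1$ amplification (synergy), $\gamma < 1$ attenuation,
$\gamma = 1$ exact linearity. The percent excess $(\gamma-1)\times 100$
expresses the same deviation as a percentage of the additive prediction.
Because $\gamma$ is a ratio of deltas it is invariant to rescaling of the
risk values; tables on a percentage or rate scale are therefore accepted
as-is, and the scale is carried through reports only as a note.

### Degenerate and boundary cases

* **Pure synergy.** If the additive delta is numerically zero
  (|additive| ≤ ε, default ε = 1e-12 on the input scale) while the combined
  delta is not, γ is unbounded. The framework reports a categorical
  `pure_synergy` marker, never a number; `percent_excess` is undefined and
  raises.
* **No effect.** If both deltas are within ε of zero, γ = 1 by convention
  (the reconstruction identity γ·additive = combined then holds trivially)
  and the report is flagged `no_effect`.
* **Mixed signs.** When the combined and additive deltas have opposite
  signs, γ is negative and its magnitude is not interpretable as
  amplification or attenuation. The signed ratio is still reported but the
  scenario is classified `mixed_sign` rather than given invented semantics.
* **Classification tolerance.** γ is compared with 1 at tolerance `tol`
  (default 1e-6) to decide amplification/attenuation/linear.

Every finite-γ report verifies the reconstruction identity
γ × additive = combined to within 1e-9 (relative to the larger delta) as an
internal consistency check; it holds by construction and a violation would
indicate a defect, not a model result.

No confidence intervals or hypothesis tests are attached to γ: the framework
is a deterministic functional of the risk source, and statistical validation
of estimated γ values is out of scope here.

## Inference

Network-sourced risks are exact posterior probabilities
$P(\text{outcome level} \mid \text{evidence})$ with evidence = context ∪
factor assignment. Two independent routes are implemented:

* `enumerate_posterior` — brute-force summation of the chain-rule joint over
  all completions; the oracle.
* `ve_posterior` — variable elimination with standard factor algebra
  (product, marginalization, evidence reduction). The elimination order is
  chosen by the min-fill heuristic with lexicographic tie-breaking, which is
  cheap, deterministic, and adequate for the ≤ ~15-variable networks this
  package targets; no junction tree or caching is built because workloads
  are single queries.

Only hard evidence is supported. Evidence with probability zero is an error
(`ImpossibleEvidenceError`), not a NaN posterior. The test suite checks the
two routes agree to 1e-9 on hundreds of random networks, and that results are
invariant to variable declaration order.

## Parameter learning

CPTs are estimated from categorical records by maximum likelihood with
optional Laplace smoothing: $\hat P(\ell \mid c) = (N_{c\ell} + \alpha) /
(N_c + \alpha K)$ with $K$ the number of child levels. `alpha` defaults to 0
(exact empirical frequencies); 1 is recommended for sparse data. Missing
values are handled complete-case *per table* — a record is dropped only from
the count tables whose variable or parents it fails to cover — which keeps
the maximum usable data; exclusion counts are logged so fits are auditable.
Unseen parent configurations yield uniform rows with a logged warning rather
than an error. Levels must be declared (network file or `--levels` sidecar)
so that levels absent from the data still receive mass under smoothing;
continuous fields must be binned by the user beforehand.

## Synthetic data

`forward_sample` draws i.i.d. records ancestrally in topological order using
one explicit `numpy` generator seeded per call (no global state); identical
seeds give byte-identical CSV output.

`build_planted_network` inverts the model to create ground truth: independent
root exposures with chosen prevalences feed a binary outcome whose CPT is

* baseline `p0` with no exposure active,
* `p0 + d_i` with exactly exposure *i* active,
* `p0 + γ* · (sum of active deltas)` with two or more active.

Applying the planted γ* uniformly to every multi-exposure row (not only the
all-exposure row) is a deliberate convention: it gives a single-parameter
ground truth under which every factor subset of size ≥ 2 also has nonlinear
effect factor γ*, which the subset tests exploit. Specs whose implied
probabilities leave [0, 1] are rejected with the violated bound named.
Evaluating the planted scenario on the exact network recovers γ* to 1e-9;
`recover_gamma` closes the loop statistically (sample → fit → evaluate) and
flags the result low-confidence when any parent configuration went
unobserved.

Recovery test bounds were calibrated empirically before being frozen: at
n = 2×10⁵ across 20 pre-registered seeds, γ̂ for γ* = 1.0 stayed within
[0.956, 1.060] and for γ* = 1.5 within [1.447, 1.587]; the test bands
[0.93, 1.07] and [1.40, 1.60] add margin beyond the observed spread.

### Fixture schemas

`crash_schema()` and `health_schema()` are invented, plausible demonstration
networks emulating a crash-report schema (weather → surface/light; physical
condition, surface and seatbelt use → severity) and a health-survey schema
(age band → BMI band; age, BMI, activity → binary disease outcome). Severity
rows are generated from multiplicative hazard factors so that fatal
probability rises strictly with DUI, snow, and no seatbelt; disease rows come
from a logistic odds model. **Their CPT values are not estimates from any
dataset**; they exist so every pipeline is exercisable offline. Consequently,
passing tests on these fixtures demonstrate correctness of the machinery, not
real-world effect sizes: the generator emulates schema shape, marginal
plausibility and planted interaction strength, but not real data's
confounding beyond independent roots, sampling bias, or missing-data
mechanisms.

### Worked-example fixtures

Two shipped risk tables encode the published road-safety worked-example
numbers so the headline quantities are recomputable without external data:
a two-factor DUI/snow table on the *delta* scale (baseline entered as 0, so
lookups return the published deltas 0.895/0.018/0.997 directly), and a
three-factor DUI/snow/no-seatbelt table with percentage-scale fatal risks
(0.259 baseline; 0.277, 0.273, 4.793 singles; 5.193 all-risk; 0.297 with
belt kept on). The two tables use different outcome definitions and scales
and are deliberately kept as separate, independently documented fixtures; no
reconciliation between their DUI deltas (0.895 vs 0.018) is attempted. Note
that published percentages are rounded from unrounded deltas: exact
arithmetic on the three-factor table gives γ = 1.0806 and 8.06% where the
rounded presentation reads 1.081 and 8.1%, and 18.75% where it reads 18.70%.

## Numerical choices

* Probabilities are double precision; CPT rows must sum to 1 within 1e-9 on
  load. Renormalization is available only as an explicit call
  (`DiscreteNetwork.renormalized()`), never applied silently.
* Level labels are case-sensitive opaque strings ("1" ≠ 1 ≠ "true").
* CPT rows are serialized row-major over parents in declared order, and JSON
  writers emit canonical key order, so files round-trip bit-identically.
* Subset analysis is guarded at 12 factors (2¹² subsets); larger scenarios
  must pass explicit subsets.
* Problem sizes in the test suite — ≤ 6-variable random networks for the
  oracle-equivalence sweep, 2×10⁵ records for learning-consistency and
  recovery checks — were chosen as the smallest sizes at which the checked
  tolerances are comfortably stable.

## Known limitations

* Hard evidence only; no soft/virtual evidence, MAP queries, approximate
  inference, continuous nodes, structure learning, or latent-variable EM.
* The synthetic generator's confounding structure is limited to independent
  roots; correlated exposures are future work.
* γ compares one all-risk configuration against one baseline; it does not
  decompose which factor pairs drive the interaction (subset analysis gives
  a coarse view).
* Risk tables are trusted as given: the framework checks presence and
  nonnegativity of configurations, not their provenance or internal
  consistency.
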