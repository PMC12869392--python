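# Methods

This note documents the models implemented in `oudtraj`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not demonstrate.

## Transition phenotyping

Three single transitions are derived per person from the dated concept
stream, each censored at the end of available data:

* **onset** — cohort entry (day 0) to the first event in the user-supplied
  OUD concept set; one record per person.
* **remission** — among persons with ≥ 1 OUD event, from the *last* OUD
  event to the first remission-coded event. For persons who never remit,
  the origin is the last observed OUD event; for remitters it is the last
  OUD event at or before the remission code. This makes the origin
  well-defined for censored and uncensored records alike.
* **relapse** — from the remission event to the first OUD event strictly
  after it. Only the first remission→relapse cycle is modelled.

Durations must be strictly positive because the start–stop risk-interval
formulation cannot represent zero-length intervals; a same-day OUD event
and remission code therefore yields a dropped record with a logged warning,
as does a remission code with no preceding OUD event (a phenotype
inconsistency worth surfacing, not silently repairing).

## Time-indexed features

Each concept (or pooled concept group) contributes five transforms
evaluated at risk-set time *t*: counts over the half-open windows
(t−30, t], (t−90, t], (t−365, t], the cumulative count up to and including
*t*, and days since the most recent occurrence at or before *t*. Fixed
conventions:

* **Window boundary.** Half-open (t−w, t]: an event exactly w days before
  *t* is excluded; an event on day *t* is included. One convention had to
  be pinned and tested; this one keeps `days_since_last = 0` consistent
  with "an event today is in every window".
* **Count scale.** The four count transforms are reported as log(1 + x), so
  hazard ratios read "per unit of log(1 + count)". `days_since_last` stays
  in days (it is a recency, not a count).
* **Missing recency.** A never-observed concept gets
  `days_since_last = horizon + 1` (a finite sentinel paired with `cum = 0`),
  keeping the design dense and monotone-interpretable instead of
  introducing NA handling into the risk sets.
* **Row splitting.** Person-period rows split at the days a used concept
  stream jumps, with features frozen at their `t_start` value. Between
  events the count features are step functions, so the splitting is exact
  for `cum` and exact up to window-expiry within a row for the windowed
  counts; splitting daily would multiply the row count ~30-fold for minimal
  information gain.
* **Static covariates** are carried unchanged on every row; categorical
  covariates expand to indicators against the most frequent level.

## Penalized survival modelling

The counting-process Cox partial likelihood with **Breslow** tie handling is
implemented directly (`oudtraj.survival._cox`): risk sets are resolved by
sorted-event-time cumulative sums, making the log-likelihood and score
O(n·p) and the exact observed information O(n·p²). Breslow was pinned
because day-resolution data produce heavy ties and cross-implementation
agreement requires naming the approximation; the engine is verified in the
test suite against R `survival::coxph(ties="breslow")`, against lifelines
on tie-free data, against finite differences, and against a brute-force
risk-set enumeration.

The lasso path minimizes −ℓ/n_events + λ‖β‖₁ by FISTA with backtracking,
warm-started down a geometric grid of 25 λ values from λ_max (the smallest
λ with all-zero solution) to 0.05·λ_max. Features are standardized
internally; coefficients are reported on the original scale; constant
columns are dropped with a logged note. λ is chosen at the minimum of the
summed held-out partial deviance over K person-level folds (the
deviance minimizer, not the 1-SE rule — the conventional default, stated
explicitly for reproducibility). Fold assignment partitions persons, never
rows, so a person's correlated intervals cannot straddle the split. KKT
conditions at the solution are asserted as an independent optimality oracle
in the tests.

Shard aggregation records, per feature, the number of shards whose CV-lasso
kept it and the arithmetic mean of exp(β) over those shards (the mean of
hazard ratios, not the exponential of the mean coefficient).
Prioritization keeps features above a selection-frequency threshold and
orders by (frequency desc, |ln mean HR| desc, name) — protective and risk
effects compete on equal footing through the |ln| magnitude. Defaults
(K = 10 folds for library use, configurable shard count, penalization of
all columns including demographics) are exposed because no canonical values
exist; the CLI uses K = 5 and 2 shards as lean defaults for desk-scale
cohorts.

The summary analysis refits a compact feature set unpenalized and reports
Wald 95% CIs and Benjamini–Hochberg q-values (statsmodels implementation).
Non-convergence yields NA estimates with a logged error; |β| > 10 triggers
a separation warning but is reported as-is rather than special-cased.
Because the nested windows of one stream (30 ⊆ 90 ⊆ 365 ⊆ cum) are
collinear by construction, the recommended summary set takes one recent
count window plus the recency per stream, which is what the package's own
summary tests fit.

## Synthetic cohorts and what they show

Event streams are inhomogeneous Poisson processes: per-person gamma frailty
(shape 2, mean 1) × per-(person, concept, 90-day block) log-normal
multipliers (σ = 0.7) × a base rate of 0.6 events per concept-year over a
730-day follow-up, with days rounded to integers and duplicates removed.
The frailty couples all of a person's streams (sicker people have more of
everything), and the block multipliers create the within-person burstiness
that exercises every transform.

Transition times are drawn by inversion from a proportional hazard
λ(t) = λ₀·exp(Σ β_f·x_f(t)) whose covariates are evaluated by the *same*
features code on the person's full event grid, piecewise-constant between
grid days — so the fitted counting-process model is correctly specified and
the planted β are the true parameters. Baseline hazards default to
5×10⁻⁴/day (onset), 2×10⁻³ (remission), 1.5×10⁻³ (relapse), giving roughly
35% onset incidence over two years with about half of onsets remitting and
a third of remissions relapsing — proportions a two-year observational
window could plausibly produce. Default planted effects: +1.0 on
`cond1_cnt_30d` (onset), +0.7 on the MAT-like drug's `rx1_cnt_90d`
(remission), +0.5 on `cond2_cum` (relapse). Observable `oud` / `rem`
marker events are appended so phenotyping can re-derive the latent truth.

What passing recovery tests show: the pipeline identifies a genuinely
planted windowed effect at n = 2000 with ≥ 90% sign-correct selection and
top selection frequency, under realistic sparsity and frailty-induced
correlation between null streams. What they do not show: robustness to
informative censoring, coding drift, vocabulary mapping error, visit-driven
observation processes, or confounding structures beyond shared frailty —
all present in real EHR data. The generator also uses integer days from
entry (no calendar structure) and a generic "survey" domain.

## Knowledge graph

Edge weights follow the evidence formulas exactly (see README for the
constants). Open points resolved here:

* **Branch precedence.** A gene may carry several evidence types; the
  piecewise score takes the first matching branch in the printed order
  (replication → cross-ancestry flag → OUD-only → MTAG → posterior →
  p-rank → ε).
* **p-rank branch.** The source expression is typographically ambiguous;
  the literal reading a_g = ln(3 + rank/e) is adopted and isolated in one
  function so it can be swapped. Note it increases with rank; under the
  cap c_max = 1 it is nearly flat in practice.
* **Indicator terms are additive**, including both mechanism bonuses when a
  pair is annotated antagonist *and* agonist; approval implies the
  late-phase term (app = 1 forces ph3).
* **Multi-pathway bridging** keeps the maximum bonus per gene (assignment,
  not accumulation) and records every supporting pathway; the global
  bridged-gene budget B_max keeps the highest bonuses, ties broken by gene
  id.
* **Defaults** ε = 10⁻⁶, c_max = 1.0, γ = 0.5, m_min = 2, B_max = 50,
  α = 0.85, approved_prior = 0: conventional damping, conservative caps,
  all exposed in `KGParams` and on the CLI.

Ranking runs Personalized PageRank on the pathway-free projection
({OUD} ∪ genes ∪ drugs) with row-stochastic transitions; dangling nodes
(drugs, and genes without drug edges) redirect their mass to the
personalization vector, which keeps Σr = 1. Power iteration stops when the
L1 change falls below 10⁻¹⁰; the default iteration cap is 200 because the
L1 error contracts by a factor α per sweep, so α = 0.85 needs ≈ 140 sweeps
to reach that tolerance. The implementation is tested against a dense
linear solve of (I − αP̃ᵀ)r = (1−α)s and against networkx's PageRank.
Alias merging lowercases names and strips a fixed salt/ester suffix list;
it collapses ingredient-versus-salt duplicates, keeps the maximum score and
unions the provenance. Drug-abuse-liability filtering is deliberately not
hard-coded: agonist candidates that are inappropriate for repurposing
should be removed by a user-supplied post-hoc filter.

## Numerical and reproducibility notes

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; equal config + seed reproduces byte-identical
  tables, ranked TSVs and manifest hashes.
* FISTA tolerance 10⁻⁶ on the relative objective change; Newton stops on
  relative gradient/likelihood change below 10⁻⁹ with step-halving, and a
  10⁻⁹ ridge stabilizes the information matrix solve.
* Score ties in the drug ranking break lexicographically by drug id;
  prioritization ties break by feature name — determinism is preferred over
  arbitrary hash order everywhere.
* Problem sizes used by the package's own experiments (n = 1000–3000
  persons, ~16 concepts, 20 replicates for recovery and null-selection
  studies) were chosen to make the statistical claims testable at desk
  scale; the pipeline itself is O(rows × features) per likelihood
  evaluation and has no structural obstacle to larger cohorts.

## Known limitations

* Single first cycle per person; competing risks and repeat
  remission/relapse cycles are out of scope.
* The summary fit reports marginal Wald inference without propagating
  selection uncertainty from the lasso stage (the two stages answer
  different questions and are kept separate).
* Large |β| estimates under separation are warned about but not penalized
  or removed.
* The knowledge graph reads pre-extracted evidence tables; it does not
  query ChEMBL/DrugBank/Reactome, and a high rank is a network-proximity
  hypothesis, not an efficacy claim.
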