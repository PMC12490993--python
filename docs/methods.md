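# Methods

## Model

The package treats a clinical cohort as `n` i.i.d. draws from a
discrete causal Bayesian network: a DAG `G` over categorical variables
plus one conditional probability table (CPT) per node, with the joint
factorising as `P(x) = Π_v P(x_v | x_pa(v))`. The causal reading is
Pearl's: an intervention `do(X = x)` deletes X's incoming edges and
clamps its CPT to a point mass, and interventional queries are
ordinary posterior queries on the mutilated network. Two assumptions
are inherited from this framework and are not tested by the package:
causal sufficiency (no unmeasured common causes) and faithfulness
(independences in the data reflect d-separations in `G`).

Missingness is modelled as a category, not an absence: every variable
that can be unrecorded carries the state label `"99"`, and all scores,
independence tests, and CPTs treat it as an ordinary level. This is a
deliberate modelling stance for registry data where non-recording is
informative (a lab never ordered is a clinical decision); the cost is
that CPT rows conditioned on `"99"` describe the observation process
as much as the biology, which matters when interpreting interventions
on heavily missing variables.

## Synthetic cohorts

Real maternity records cannot be redistributed, so the study-scale
generator stands in for them. It emulates:

* **Scale and shape** — 1,808 rows over 62 categorical variables with
  clinically quantised state spaces (BMI classes, parity bands,
  birth-weight categories, trimester bands, yes/no history fields).
* **Dependence structure** — a hand-written synthetic knowledge graph
  of 75 directed edges following the antenatal care pathway
  (demographics → history → diagnosis → treatment → delivery →
  neonatal → postnatal). It is a plausible clinical DAG, not an
  estimate from any dataset. Nine of the 62 variables
  (Instrumental_delivery, HbA1c_post, History_of_Miscarriage,
  History_of_PET, Polyhydramnios, Macrosomia, Induction_of_labour,
  Shoulder_dystocia, Jaundice_in_infant) are fillers completing the
  node-level expansion of grouped source fields; both schema and edge
  list are replaceable through the pipeline config.
* **Parameters** — CPT rows drawn from a symmetric Dirichlet over the
  non-missing states (zero mass on `"99"`: the structural model
  generates complete records). The default concentration `α = 0.5`
  gives skewed rows, hence detectable dependences at cohort scale;
  `α → ∞` recovers uniform rows, which tests exploit as an oracle.
* **Missingness** — an overlay applied after sampling. MCAR masks a
  variable at a flat rate; MAR looks the rate up by the observed
  values of designated conditioning variables. The study-scale preset
  assigns rates by variable class: postnatal/neonatal labs high
  (0.72–0.78 for neonatal hypoglycaemia, neonatal trauma, and the
  2-hour postprandial test), history fields 0.15, delivery outcomes
  0.18, diagnostics 0.12, treatments 0.10, demographics 0.04, and a
  MAR mechanism on Depression and Previous_Bariatric_Surgery keyed on
  patient type (0.45 public vs 0.20 private) standing in for
  documentation differences between care settings.

What the generator does **not** emulate: real marginal prevalences,
selection into the cohort, temporal/cohort effects, measurement error,
or missingness depending on the missing value itself (MNAR). Passing
tests therefore demonstrate that the machinery is correct and that
recovery is possible under faithful, causally sufficient conditions —
not that comparable recovery is expected on real records.

## Structure learning

* **G² test**: likelihood-ratio chi-square, degrees of freedom
  `(r_x−1)(r_y−1)` summed over non-empty conditioning strata; a
  variable with a single observed level renders the test
  uninformative (treated as independence). Default `α = 0.05`.
* **HC/TABU** start from the empty graph; moves are single-edge
  add/delete/reverse; ties between equal-score moves break
  lexicographically by operation then (parent, child), so runs are
  reproducible. TABU keeps a list (default length 10) of recently
  visited structures and accepts the best non-tabu move even when
  non-improving, returning the best structure seen. `max_parents` is
  unlimited by default — the BIC penalty is the regulariser.
* **PC-Stable** copies the adjacency sets at the start of each level,
  making the skeleton independent of column order; orientation is
  v-structures then Meek rules 1–3 (sufficient for closure without
  background knowledge). Conflicting v-structures are resolved
  first-come in deterministic node order.
* **GS** estimates Markov blankets (grow then shrink), symmetrises by
  the AND rule, resolves direct neighbours by exhaustive subset
  search within the smaller blanket, and orients like PC.
* **MMHC** restricts hill climbing to the MMPC skeleton (max-min
  candidate selection, backward pruning, AND-rule symmetry).
* **CPDAG → DAG**: randomised Dor–Tarsi consistent extension. The
  admissible-sink choice is uniform at each step under the seed,
  which reaches every member of the equivalence class but is not an
  exactly uniform draw over it (exact uniformity would require
  counting extensions). Finite-sample constraint-based output is not
  always a valid CPDAG; when no consistent extension exists, ensemble
  assembly falls back to forced orientation — undirected edges
  oriented in random order, each in a direction preserving acyclicity
  — and records a warning. Externally supplied graphs that cannot be
  extended are excluded from the ensemble instead, with a warning.

## Model averaging

Four-step insertion with a count threshold (default 4, the
majority-vote cut-off of the study design): (1) directed edges by
descending count — skip if the reverse is already present (deferred),
reverse-and-add if insertion would close a cycle; (2) surviving
undirected edges by descending count — skip if the pair is already
directed, otherwise orient toward the direction with the higher
directed count (lexicographic on ties); (3) re-examine the deferred
edges by descending count — under this reading they remain excluded,
and the audit log records the rule applied to every eligible edge.
Equal counts process in lexicographic (parent, child) order. Reversed
edges are traceable in the audit log but not distinguished in
downstream inference; users weighing direction uncertainty should
consult the log and the threshold sweep.

## Evaluation

* `i` (reference independencies) is defined as the number of
  non-adjacent reference pairs, `|V|(|V|−1)/2 − a`. With the
  alternative reading `i = |V|(|V|−1)/2` the confusion identity
  `TN + FP = i` fails and the empty graph no longer scores 0; that
  variant is kept behind `bsf(..., literal_i=True)` for comparison.
* SHD counts one difference per node pair (missing adjacency, extra
  adjacency, or orientation mismatch).
* Orientation errors count as false negatives, not false positives:
  FP is reserved for adjacencies the reference lacks entirely, which
  is what keeps `TN + FP = i` exact.
* LL/BIC use natural logarithms and maximum-likelihood CPTs fitted on
  the same data, with `0·ln 0 := 0`; free parameters count every
  state, including `"99"`.
* Bootstrap CIs resample the node-pair comparison universe with
  replacement (percentile interval, default B = 1000). This is a
  declared stand-in — resampling rows or edges would be equally
  defensible — and is deterministic under its seed. Resamples on
  which a metric is undefined (e.g. no reference edge drawn) are
  redrawn and counted.

## Inference and sensitivity

Variable elimination with min-fill ordering and barren-node pruning;
exactness is checked in the tests against brute-force joint
enumeration (tolerance 1e-9). CPTs for inference are fitted with
Laplace smoothing (`α = 1`) so queries never hit zero-probability
evidence artefacts, while LL/BIC scoring stays at the MLE (`α = 0`,
uniform fallback for unobserved parent rows).

Sensitivity analysis is one-way CPT perturbation: each entry of each
ancestor's CPT is shifted by ±δ (default 0.05, truncated to [0, 1]
with the truncation noted) with proportional co-variation of the rest
of the row; a node's sensitivity is the maximum absolute change
induced in any state of the target's posterior, and nodes are ranked
by it. Max (rather than sum) over entries is the declared
aggregation. Nodes with no directed path to the target score exactly
0. The analysis runs on the target's ancestral subnetwork, which is
what makes per-entry re-inference affordable at 62 nodes.

## Problem sizes and determinism

Default problem sizes — cohort 1,808 × 62, parameter-recovery studies
at n = 5,000 over 10 nodes and 10 seeds, 50 random 8-node networks
for the inference oracle — were chosen so the full pipeline completes
in well under a minute on one CPU while leaving comfortable
statistical margins (binomial standard-error bands at these n are a
few percentage points). Every random draw flows through an explicit
integer seed: generators, learners, extensions, bootstraps, and the
pipeline all reproduce bit-identically under a fixed configuration.

## Known limitations

* The consensus DAG inherits orientation artefacts from forced
  extensions and cycle reversals; the audit log is the mitigation,
  not a cure.
* G²-based learners assume adequate cell counts; with 6-level
  variables and deep conditioning sets the chi-square approximation
  thins out, which is why the degrees-of-freedom adjustment drops
  empty strata.
* Sensitivity values are one-way; interactions between simultaneous
  parameter changes are not explored.
* No MNAR mechanism, no latent-variable learning (FCI-style), no
  counterfactual (twin-network) queries.
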