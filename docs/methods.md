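# Methods

This note documents the model implemented by `ndamda`, the choices made
where the construction was genuinely open, the synthetic benchmark that
stands in for curated data, and the method's known limitations.

## Model

The method treats miRNA–disease association prediction as link ranking on
a pair of similarity networks tied together by the binary association
matrix `Y` (miRNAs × diseases). Its working assumption is the standard
one in this literature: functionally similar miRNAs tend to associate
with semantically similar diseases. Three stages follow.

### 1. Similarity integration

*Disease semantic similarity.* Each disease is described by one or more
hierarchical descriptor codes (dot-separated tree numbers). Truncating a
code segment by segment enumerates the term's ancestors; the union over a
disease's codes, with terms reached through several codes merged, is its
ancestor DAG. Model 1 gives the disease's own terms contribution 1 and
propagates `D(t) = max{Δ·D(t′)}` over children `t′` within the DAG, so
contribution decays geometrically with distance from the disease and
multiple paths resolve to the shortest. Model 2 replaces the decay with
corpus-level information content, `D*(t) = −log(c(t)/N)`: a term present
in every disease's DAG contributes nothing, a rare term contributes much.
Both models score a pair by the shared-term contributions normalised by
the two semantic values (sums over each DAG), giving unit self-similarity
and values in [0, 1].

*Gaussian interaction-profile kernels.* A node's profile is its row (miRNA)
or column (disease) of `Y`. The kernel bandwidth adapts to network
density: `γ = γ′ / mean‖IP‖²` over the axis being compared. Profiles of
all zeros are legal for individual nodes (their pairwise kernel is 1, the
zero-distance value), but an entirely empty `Y` leaves `γ` undefined and
is an error.

*Integration.* A miRNA pair uses the curated functional-similarity value
whenever both names appear in the supplied matrix — including when that
value is 0, since an observed zero is information, not absence — and the
kernel otherwise. A disease pair uses the mean of the two semantic models
when both diseases have descriptors, the kernel otherwise.

### 2. Distances and confidence

Similarities invert elementwise into raw distances `D = 1/S`, floored at
`S ≥ ε` (`ε = 1e-12`) because kernel values can underflow to exactly 0.
Each node's mean raw distance `σ_i` (self-distance included; a flag
excludes it) rescales distances into `D_adj[i,j] = D[i,j]/(σ_i σ_j)`,
which compensates for nodes that are globally close to everything.

One algebraic point worth recording: `D_adj` is *equivariant*, not
invariant, under uniform rescaling of `S` — scaling `S` by `c` scales
`D_adj` by exactly `c` (the `σ` product contributes `c²` against the raw
distance's `1/c`). Every downstream quantity is rank-based, so
confidences scale uniformly and ranks, precisions and final scores are
exactly invariant; the tests assert both facts.

For a disease with known miRNA set of size `R` (its *richness*), a
candidate miRNA's confidence is its mean adjusted distance to all `n_m`
miRNAs minus its mean adjusted distance to the known set. The known set's
mean includes the candidate itself when the candidate is a known partner;
this only affects training positives, which are never ranked as
candidates in evaluation. Richness 0 leaves the confidence undefined and
is an error at this level; the scoring layer handles it by fallback.

### 3. Score conversion

Within one context, candidates are sorted by descending confidence and
each receives `Precision = R/H`, where `H` counts candidates with
confidence at-or-above (ties share the last index of their group, the
deterministic and conservative choice). The value exceeds 1 at ranks
above `R`; it is implemented literally as a rank conversion, not
renormalised into a probability. The conventional precision-at-H (known
positives in the top `H` over `H`) is available behind
`standard_precision=True` for sensitivity analysis only. A pair's final
score averages its two one-sided precisions; pairs whose miRNA (or
disease) has no known partners fall back to the defined side alone, and
pairs with neither side defined score 0 (logged).

For a disease with *no* known associations (the new-disease setting), the
ranking uses the disease-side precision alone, with kernels recomputed
from the masked network by default.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `delta` | 0.5 | semantic decay per DAG layer, in (0, 1]; the customary value in decayed-contribution similarity |
| `gamma_prime_m`, `gamma_prime_d` | 1.0 | dimensionless kernel adjustment; 1 leaves the bandwidth entirely to the density normalisation |
| `epsilon` | 1e-12 | similarity floor before inversion; only guards underflow |
| `log_base` | natural | base of the information-content log; changing it rescales model-2 numerator and denominator jointly and matters only through mixing with model 1 |
| `include_self_distance` | true | whether `σ_i` includes `D[i,i] = 1` |
| `kernel_mode` | refit | per-fold kernel recomputation in CV; `frozen` reuses full-network kernels and is faster but lets the held-out pair leak through the profiles |

## Evaluation protocols

Leave-one-out masks each known association in turn; the recomputed score
of the held-out pair is ranked against the candidate pairs (pairs with no
known association in the full network — other training positives are
excluded). Global ranks against all candidates, local against the
held-out disease's column only; a disease whose column has no candidates
is skipped with a warning. Repeated k-fold shuffles the associations
(seeded), masks each of k near-equal folds jointly (sizes differ by at
most 1) and reports mean ± across-repeat SD of the AUC. The per-sample
statistic `(c + 1 − r)/c` (rank `r` among `c` candidates, mid-rank ties)
averages to the Mann–Whitney AUC and equals the exact area under the
normalised rank-threshold ROC curve; both routes are computed and
cross-checked in tests, the sweep against scikit-learn's pooled ROC.

The default of 10 repeats for k-fold keeps the scheme proportionate to
the benchmark sizes used here; it is a CLI flag (`--repeats`) for anyone
wanting the heavier traditional choice of 100.

## Synthetic benchmark

Curated inputs of the original scale (a 495 × 383 curated association
snapshot, the published functional-similarity matrix, the full descriptor
vocabulary) are not redistributable in this package, so the generators
plant the structure the method is designed to exploit and make every
stage testable end to end. miRNAs and diseases are partitioned
round-robin into matched clusters; associations are Bernoulli draws,
denser inside matched blocks; functional similarity is truncated-normal
noise around a high within-cluster and low between-cluster mean, with a
fraction of miRNAs omitted from the matrix to exercise the kernel
fallback; descriptor codes come from a rooted tree in which same-cluster
diseases share their first `depth − 1` segments, with optional second
codes under other branches. Defaults: 200 miRNAs × 100 diseases, 5
clusters, within/background association probabilities 0.12/0.005 — chosen
so the expected density (≈2.8%) matches the curated human dataset —
functional-similarity means 0.6/0.15 with SD 0.1, tree depth 3 with
branching 25. Every miRNA and disease is guaranteed at least one
association (a matched-block partner is forced in if a row or column came
up empty, and logged) because training contexts need richness ≥ 1.

What the benchmark does *not* emulate: the heavy-tailed degree
distribution of curated databases (literature attention concentrates on a
few cancers and famous miRNAs), correlated ascertainment between the
association and similarity layers, realistic descriptor-vocabulary
structure, and name-level idiosyncrasies. Passing the planted benchmark
therefore shows the pipeline recovers the relational signal it assumes,
not that it attains any particular accuracy on curated human data.

A deterministic 8 miRNA × 6 disease toy instance accompanies the
generators (in memory and as shipped files); its intermediates are
checkable by hand — orthogonal unit disease profiles give kernel value
`e⁻²` at `γ′ = 1`, sibling diseases under a shared parent give model-1
similarity 1/3 at `Δ = 0.5`, and two unassociated miRNAs exercise the
missing-side fallback.

## Numerical choices

- Ranking ties in output files break alphabetically by miRNA name, so
  written predictions are reproducible; numeric evaluation never breaks
  ties, using mid-ranks instead (unbiased AUC).
- `H` in the precision conversion is computed by binary search against the
  sorted confidence vector; tied confidences share the group's largest
  `H`.
- All generators are pure functions of (config, seed) with
  per-generator salted streams, so outputs are byte-identical across runs
  and insensitive to the order in which generators are called.
- Exact confidence ties can be regrouped by reordered floating-point
  summation (e.g. after permuting the index); rank-based results are
  exact in real arithmetic but can move by a few ranks on tiny instances.

## Case-study fixtures

The five bundled evidence tables transcribe published top-50 prediction
lists (breast, oesophageal, lymphoma, prostate, hepatocellular) with
each row's confirming databases or an "Unconfirmed" marker; `casecheck`
recomputes confirmed counts at top-10/20/50 and compares user predictions
against the published lists. The transcriptions normalise minor
typographical artifacts of the printed tables (broken tags, stray spaces,
mixed case) without altering any row's confirmed status.

## Limitations

- Scores are comparative ranks; `R/H` values above 1 have no
  probabilistic reading.
- The method inherits the degree bias of confidence-vs-mean scoring:
  miRNAs with many known diseases are systematically favoured.
- Diseases whose associated miRNAs are scattered randomly in the
  similarity networks gain nothing from the distance adjustment.
- LOOCV with per-fold kernel refits is quadratic in network size times
  the number of associations; the frozen mode is the practical choice for
  large grids and is what the shipped benchmark uses.
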