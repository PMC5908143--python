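# ndamda

Network-distance analysis for miRNA–disease association prediction.

Experimentally confirming which microRNAs are involved in which human
diseases is slow and expensive, so computational ranking of candidate
miRNA–disease pairs is a standard first pass for wet-lab prioritisation.
`ndamda` implements a network-distance method for this problem: it fuses a
curated binary association network with miRNA functional similarity,
disease semantic similarity over descriptor DAGs and Gaussian
interaction-profile kernels, and ranks every unobserved pair by how much
closer it sits to the known associations than to the network at large.

## Method

Let `Y ∈ {0,1}^(n_m × n_d)` be the known miRNA–disease associations.

**Similarity layers.** Disease terms are located in a hierarchy by
dot-separated descriptor codes; prefix truncation yields each disease's
ancestor DAG. Two semantic models score a disease pair by its shared
ancestors: model 1 weights an ancestor `t` by a decayed contribution
`D(t) = max{Δ·D(t′) : t′ child of t}` (with `D = 1` on the disease's own
terms, `Δ = 0.5` by default), model 2 by its information content
`D*(t) = −log(c(t)/N)` where `c(t)` counts the disease DAGs containing `t`.
Both normalise the shared contribution by the two semantic values
`DV = Σ_t D(t)`. Gaussian kernels over interaction profiles (rows/columns
of `Y`), `KS(i,j) = exp(−γ‖IP_i − IP_j‖²)` with `γ = γ′ / mean‖IP‖²`,
fill in pairs without curated similarity; integration takes the curated
value where present (functional similarity for miRNAs, the mean of the two
semantic models for diseases) and the kernel elsewhere.

**Scoring.** Similarities invert into raw network distances `D = 1/S`;
each node's mean raw distance `σ_i` normalises them into adjusted
distances `D_adj[i,j] = D[i,j]/(σ_i σ_j)`. For a disease with `R` known
miRNAs, a candidate miRNA's confidence is its mean adjusted distance to
all miRNAs minus its mean adjusted distance to the known set — positive
when the candidate is closer to the disease's miRNAs than average. A
rank conversion `Precision = R/H` (richness over the number of candidates
ranked at-or-above) makes confidences comparable across contexts of
different richness, and a pair's final score averages its miRNA-side and
disease-side precisions:

```
P(m_i, d_j) = ( Pr_{d_j}(m_i) + Pr_{m_i}(d_j) ) / 2
```

**Evaluation.** Global/local leave-one-out and repeated five-fold
cross-validation rank each held-out association against the candidate
pairs; the AUC is the mean fraction of candidates a validation sample
outranks (a Mann–Whitney statistic with mid-rank ties). Kernels can be
refit per fold (default; no leakage through the profiles) or frozen.

## Worked example

```python
from ndamda import NDAMDA
from ndamda.synthetic import SyntheticConfig, generate_bundle
from ndamda.evaluation import global_loocv

cfg = SyntheticConfig(n_mirnas=40, n_diseases=20, n_clusters=4,
                      within_cluster_assoc_prob=0.3,
                      background_assoc_prob=0.02, seed=11)
bundle = generate_bundle(cfg)
model = NDAMDA(bundle["adjacency"], bundle["functional_similarity"],
               bundle["descriptors"])
results = model.fit()
print(results.summary())
print(results.top_predictions("disease-001", k=5).to_string(index=False))
print(f"global LOOCV AUC: {global_loocv(model, kernel_mode='frozen').auc:.4f}")
```

prints

```
Network-distance association model (NDAMDA)
============================================
miRNAs:            40
diseases:          20
known associations:    72  (density 9.00%)
delta:             0.5
gamma' (miRNA):    1.0
gamma' (disease):  1.0
epsilon:           1e-12
precision rule:    R/H
--------------------------------------------
final score: min 0.0375  median 0.1714  max 4.0000
 rank   mirna    score
    1 mir-009 1.875000
    2 mir-005 0.666667
    3 mir-001 0.425000
    4 mir-013 0.416667
    5 mir-033 0.380952
global LOOCV AUC: 0.8368
```

The top-ranked candidates for `disease-001` are dominated by miRNAs from
its planted cluster; note the `R/H` conversion can exceed 1 at ranks above
the disease's richness — scores are comparable ranks, not probabilities.
The LOOCV AUC of 0.84 says a held-out true association outranks ~84% of
the unobserved pairs.

The same pipeline is scriptable from the shell:

```
ndamda synth --config synth.yaml --out-dir data/
ndamda predict --associations data/associations.tsv --fs data/fs.tsv \
    --descriptors data/descriptors.tsv --out scores.tsv
ndamda evaluate --associations data/associations.tsv --fs data/fs.tsv \
    --descriptors data/descriptors.tsv --scheme global-loocv --out cv.json
ndamda casecheck
```

`ndamda casecheck` reports the confirmed-evidence counts of the five
bundled published case-study tables (breast, oesophageal, lymphoma,
prostate and hepatocellular top-50 lists) and, given your own predictions,
their overlap with those lists.

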