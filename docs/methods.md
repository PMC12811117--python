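# Methods

## The problem

Cardiovascular risk emerges from interactions among genes, pathways,
phenotypes, medications, environmental exposures, and — distinctively here
— quantitative imaging traits of the heart and aorta.  `heartkg` builds a
directed, typed, property-carrying knowledge graph (KG) over twelve entity
types, embeds every node with a directed variational graph auto-encoder
(DVGAE), and runs the downstream battery: gene–disease and drug–disease
link prediction, candidate ranking, hypergeometric pathway enrichment,
druggability annotation, PageRank centrality, and node-type ablation.

Formally the KG is the tuple (N, E, N_p, E_p): nodes with scalar
properties and directed typed edges with scalar properties.  Direction is
semantic and never auto-symmetrized; imaging traits enter as `cmr` nodes
linked to anatomical regions, with per-individual trait values stored on
the `individual -> cmr` edges, not on the trait node.

## Harmonization

Source databases disagree on surface labels ("congestive heart disease"
vs. "left ventricular failure" vs. "heart failure").  Harmonization
normalizes a raw label (lowercase, strip punctuation, collapse whitespace
— fixed in that order, and idempotent) and matches it against a per-type
synonym dictionary in which no synonym may point at two canonical labels.
A miss is returned explicitly as `Unmapped(normalized)` rather than
silently dropped.  Inter-database conflicts (same node pair, contradictory
relations) are both stored; the duplicate-edge policy collapses only exact
(source, target, relation) repeats, keeping first-seen properties and
logging the collision.

## Imaging-derived phenotypes

Closed forms, with fixed units (areas cm², aortic areas mm², lengths cm,
volumes ml, masses g, pressures mmHg):

* biplane area–length atrial volume `V = (8 / 3π) · A_2Ch · A_4Ch / L`;
* Du Bois body surface area `BSA = 0.007184 · height^0.725 · weight^0.425`;
* left-ventricular mass = myocardial volume × 1.05 g ml⁻¹;
* linear strain `E_dir = ΔL_dir / L_dir` (signed; antisymmetric in ΔL);
* BSA indexing = value / BSA;
* aortic distensibility = `(A_max − A_min) / (A_min · PP)` on the
  10⁻³ mmHg⁻¹ scale.  The distensibility inputs (segmented maximum and
  minimum aortic cross-sections, pulse-wave central pulse pressure) are
  standard; the exact expression is the conventional relative area change
  over pulse pressure, a design choice flagged here because sources often
  leave it implicit.

Strain traits are stored in both raw and BSA-indexed form under distinct
trait names, since convention differs between cohorts.

## The DVGAE

A variational graph auto-encoder whose encoder consumes node type, node
properties, edge properties, and edge direction.

**Featurization.** Node features are the 12-way one-hot type concatenated
with one z-scored column plus one presence flag per numeric node property
(missing → 0, flag 0; zero-variance columns → 0).  Edge features are
z-scored numeric edge properties.  The encoder input additionally
concatenates a learned per-node embedding (default width J): in a graph
whose nodes are otherwise anonymous within a type, message passing alone
cannot distinguish two genes with similar neighborhood type-profiles, and
link-level generalization is impossible without a node-identity channel.
This is the graph-featureless analogue of giving a VGAE identity input
features, except the identity code is learned jointly.

**Direction and edge properties.** Each graph-convolution layer aggregates
in-neighbors and out-neighbors with separate weight matrices (plus a self
path), so direction survives the encoder.  Every edge carries a learned
scalar gate `sigmoid(w·e_feat + b)` that modulates its message in both
channels.  Two layers by default, hidden width 2J, ReLU.

**Heads and sampling.** Two linear graph-convolution heads produce μ and
log σ² per node (σ via exponentiation, so σ > 0 by construction; log σ²
clipped to ±10 for numerical safety).  Sampling is the standard
reparameterization z = μ + σ ⊙ ε.

**Losses.**

* reconstruction (per observed edge set E⁺):
  `L_recon = −(1/|E⁺|) Σ log(σ(z_uᵀ z_v) + ε)`, ε = 1e−15;
* KL to the standard normal, per node
  `−½ Σ_j (1 + log σ_j² − μ_j² − σ_j²)`, summed over nodes;
* total `L_total = L_recon + L_KL / N`, N the node count.

The decoder is the symmetric inner product `p(u→v) = σ(z_u·z_v)`; the
package keeps it as-is and confines directionality to the encoder — an
acknowledged tension, since the decoder cannot distinguish u→v from v→u.

**Training.** The edge set is split 70/30.  One epoch is a pass over
shuffled positive-edge mini-batches (default 512) with fresh 1:1 sampled
negative non-edges per batch; negatives supply the contrastive signal
without which the inner-product objective is unbounded.  The optimizer is
Adam (hand-written, as is all backpropagation — the package has no deep
learning framework dependency), and message passing during training sees
only the training edges.  Two numerical choices matter:

* *KL normalization.*  The per-node KL is **averaged** over nodes before
  the further 1/N in the total — the normalization the standard VGAE
  toolchain implementations use.  The alternative (per-node KL entering
  the total at full weight) collapses the posterior: with J = 50 that
  penalty rivals the entire attainable reconstruction gain, the optimizer
  settles at μ ≈ 0 where every pair scores 0.5, and the validation total
  then *rises* whenever the fit improves, inverting lowest-validation-loss
  model selection.  With the mean normalization, training, the per-epoch
  validation trace, and grid selection all minimize one objective, and the
  trace decreases monotonically on reconstructible graphs.
* *Gradient of the ε-stabilized log.*  The update uses the exact
  cross-entropy gradient `σ(s) − 1`; the ε in the reported loss is
  numerical stabilization only.

**Model selection.** Grid search over learning rate {0.001, 0.01, 0.1},
epochs {50, 100, 200}, latent dimension {25, 50, 100}; per-epoch
validation loss is the total loss on validation positives plus 1:1 fixed
sampled negatives; lowest final validation loss wins, ties broken by grid
order.  The shipped default is the selected configuration lr 0.001,
100 epochs, J = 50.  After selection the winner is refit on the full edge
set to produce final embeddings ("final model"); pipelines that evaluate
held-out edges use the split-trained winner instead.

**Evaluation.** Edge-wise accuracy = |original ∩ reconstructed| /
|original| with the reconstructed set = candidate pairs decoding to
p ≥ 0.5 (full ordered-pair enumeration up to 2,000 nodes; original plus
sampled negatives beyond).  Training is bit-reproducible at fixed seed.

## Link prediction

An (anchor disease, partner) pair is the concatenation (anchor first) of
the two μ vectors, length 2J.  Partners in the curated positive list get
label 1, the curated negative list 0; everything else is the unlabeled
pool and never enters training.  By default the labeled pairs' direct
edges are removed from the embedding graph before training the DVGAE, so
the classifier cannot read the answer off the edge it is asked to predict.

Three families — random forest, RBF-kernel SVM (Platt-calibrated
probabilities), and a feed-forward network — are compared by stratified
five-fold cross-validation with small published-default hyperparameter
grids searched on training folds only (inner 3-fold).  Out-of-fold
probabilities are pooled before computing TP/TN/FP/FN, accuracy
(TP+TN)/(TP+TN+FP+FN), sensitivity, specificity, and AUC.  Accuracy picks
the deployed family; exact ties fall to svm > random_forest > ann.  The
winner is refit on all labeled pairs and ranks the unlabeled pool by
predicted probability, ties broken lexicographically.

## Analytics

* **PageRank**: damping 0.85, tolerance 1e−10, dangling mass uniform,
  scores normalized to sum 1 (via networkx; oracle-tested against dense
  power iteration).  Reported scores are the normalized stationary
  distribution; analyses that print unnormalized magnitudes are not
  matched numerically, only ordinally.
* **Enrichment**: upper-tail hypergeometric, inclusive of the observed
  overlap; universe defaults to all gene nodes in the KG (override
  accepted); Benjamini–Hochberg step-up across tested sets.
* **Druggability**: a gene is druggable iff it has ≥ 1 interaction of type
  agonist, inhibitor, modulator, activator, or antibody; other types
  (e.g. binder) are discarded first.
* **Cosine validation**: cos θ = A·B/(‖A‖‖B‖) between a predicted
  medication's embedding and those of indicated medications.
* **Ablation**: the same pipeline, same seeds, run on the graph with a
  node type removed; paired reports plus top-k overlap.  Pathway-count
  differences between scenarios are compared with a 2×2 chi-squared test
  without continuity correction (matching the plain textbook statistic).

## The synthetic generator

The generator emulates the statistical shape of the real multimodal KG —
never its biological content.  Twelve node types at the real graph's
relative magnitudes (~1/20 scale; genes ≫ individuals ≫ medications ≫
pathways; 1,500 nodes and a 12,000-edge target by default), a directed
schema of legal type pairs, individual nodes carrying sex/age/BMI/
ethnicity/BSA, and imaging values on `individual -> cmr` edges.

Mechanism: every node draws a ground-truth latent vector with a decaying
variance spectrum (dimension j weighted `exp(−j/2)`, effective rank ≈ 4 of
50).  Each schema-legal relation receives a weight-proportional edge
budget (capacity-capped relations hand surplus to the rest), filled by the
top-scoring pairs under the latent inner product — i.e. an edge exists
where the sigmoid of the scaled dot product clears the calibrated
per-relation cutoff.  Because edges are inner-product threshold events, a
dot-product decoder is correct by construction and reconstruction failures
indicate implementation bugs.  The decaying spectrum is essential, not
cosmetic: with an isotropic rank-50 ground truth, the ~10 observed edges
per node cannot pin down a node's latent, and no rank-50 method — verified
with a direct logistic matrix-factorization oracle — generalizes to
held-out edges.

Planted structure around one anchor disease (a hub: its latent norm is
scaled ×1.5): positively correlated genes (ρ = 0.9; known associations,
of which a stated number are withheld from both the graph and the labels
as recovery targets), mildly anti-correlated curated negatives (ρ = −0.3 —
"no known association" is weak avoidance, not opposite coupling),
correlated bridge phenotypes that connect the cluster indirectly, and
indicated/contraindicated medications.  Effect sizes were calibrated
against the ground-truth oracle (ranking by true latent dots), not against
any model output: at ρ = 0.7 even the oracle cannot separate withheld
pairs from decoys at the documented level, so no implementation could.
A `ledger.json` records every latent and planted truth for assertions.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage structure among genes, realistic degree
heterogeneity and database ascertainment bias, noisy/contradictory labels,
covariate-driven confounding in individuals, or any real pharmacology.
Recovery of planted structure demonstrates implementation correctness and
statistical sanity, not clinical validity.

## Problem sizes used in the shipped checks

Reconstruction checks run on the ~500-node / ~5,000-edge variant of the
generator; pipeline-recovery checks on the 1,500-node / ~12,000-edge
default; analytic oracles on graphs up to 50 nodes and universes up to 25
genes.  These sizes make the full battery comfortably reproducible on a
single CPU while leaving every qualitative conclusion unchanged at larger
scale.

## Known limitations

* The symmetric decoder cannot represent asymmetric link probabilities;
  direction influences results only through the encoder.
* Validation-loss model selection uses the unweighted total loss; with
  large J its KL component can dominate comparisons between latent sizes.
* The SVM's Platt-calibrated probabilities saturate on well-separated
  training sets, which coarsens ranking among very confident candidates.
* PageRank magnitudes are normalized; ordinal comparisons only against
  reports that print unnormalized scores.
* The generator's planted effects are strong and clean by design;
  real curated labels are noisier in both directions.
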