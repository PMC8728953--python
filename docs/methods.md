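# Methods

## The model

The package scores target–disease pairs on a heterogeneous network over
three entity sets — drug-targeted proteins ("targets", T), diseases (D) and
drugs (M) — connected by three binary association layers (adjacency
matrices TDA: target–disease, TDI: target–drug, DDA: disease–drug) and
per-type similarity layers. A random-forest regression model is trained on
nine pair features; its ensemble-mean output for an unconfirmed pair is
read as the confidence that the pair is associated.

### Similarity layers

Each entity type carries a *topological* similarity derived from its binary
association profiles by the Gaussian interaction-profile (GIP) kernel

    S[i, j] = exp(−k · ‖p_i − p_j‖²),   k = k′ / mean_l ‖p_l‖²,

with bandwidth scale k′ = 1 (the standard choice for GIP kernels on
interaction profiles). Disease and target topological similarities come
from the columns and rows of TDA; the two drug similarities from the
columns of TDI and DDA. The effective bandwidth is recomputed from the
supplied profile matrix on every call, never cached across masked and
unmasked variants of TDA.

Targets and diseases additionally carry a *semantic* similarity supplied as
input (for real data: the mean of two ontology-derived disease similarities,
and the mean of sequence and functional similarity for targets; computing
those upstream similarities is out of scope). Semantic and topological
layers are merged by an entropy rule: the Shannon entropy of each row
(natural log; 0·log 0 := 0; zero-sum rows get entropy 0) measures how
diffuse that entity's similarity profile is, and for every row the matrix
with the *lower* entropy — the more concentrated, less "random" one — is
selected. Entities split into a semantic set A (ties go to A) and a
topological set B; the A×A block comes from the semantic matrix, B×B from
the topological one, and within the A×B cross block the same entropy
comparison on the rectangular sub-rows splits A into A_a (semantic) and A_b
(topological). The B×A block is defined as the transpose of A×B, which
makes the result symmetric by construction; every entry of the fused matrix
equals the corresponding entry of one of the two inputs. When B is empty
the cross-block rows are zero-width, both entropies are 0 and the tie rule
sends all of A to A_a. The base of the logarithm only rescales all
entropies by a constant, so the partition — and hence the fusion — does
not depend on it.

### Pair features

For a pair (t_i, d_j), with TTS/DDS the fused target/disease similarities
and MMS_T/MMS_D the drug similarities:

* **fea1, fea2** — mean similarity between the query disease (target) and
  the diseases (targets) *not* associated with the query target (disease).
* **fea3** — nearest-neighbor path score: with a the target most similar
  to i (excluding i) and b the disease most similar to j (excluding j),
  the sum TTS[i,a]·TDA[a,j] + TDA[i,b]·DDS[b,j] +
  TTS[i,a]·TDA[a,b]·DDS[b,j]; bounded by 3. Argmax ties break to the
  smallest index for determinism.
* **fea4** — over drugs co-associated with both query entities
  (TDI[i,k] = 1 and DDA[j,k] = 1), the maximum ratio L[j,k]/H[i,k] of the
  average disease–drug to average target–drug path weight, where
  H[i,k] = (TDI·MMS_T)[i,k] normalised by the number of i's drugs with
  nonzero similarity to k (L analogous). H > 0 is guaranteed for
  co-associated drugs because MMS has a unit diagonal.
* **fea5–fea9** — average edge-weight product over all admissible
  meta-paths of a fixed pattern between i and j: target–target–disease,
  target–disease–disease, and the three length-3 patterns
  (t–t–t–d, t–t–d–d, t–d–d–d). Each divides the weighted path sum by the
  number of admissible paths, so values stay in [0, 1] when the similarity
  weights do.

Empty sets and 0/0 averages evaluate to 0: absence of evidence contributes
the minimum and keeps all features finite. Self terms (the query entities
appearing inside their own neighborhoods or path positions, e.g. x = i in
fea5 via the unit diagonal of TTS) are *kept* by default, following the
printed set definitions literally; an `exclude_self` switch removes the
query entities from every neighborhood and intermediate position, which the
vectorised implementation realises by inclusion–exclusion on the matrix
products (valid because both similarity matrices have unit diagonals). See
"Protocol choices" for why the evaluation experiments turn this switch on.

All nine features are validated against independent literal-definition loop
implementations (`m2pp.reference`) on randomly generated
6-target/6-disease/5-drug networks, including the exclude-self variants.

### Scoring model

A regression forest on the nine features with the 0/1 association labels
as regression targets: 500 trees and mtry = ⌊n_features/3⌋ = 3 candidate
variables per split by default, matching the R randomForest regression
defaults for this design. Scores are ensemble means, hence in [0, 1].

## Evaluation protocols

**Repeated stratified five-fold CV.** The known associations are the
positives; an equal number of unconfirmed (TDA = 0) pairs is sampled
uniformly without replacement as negatives, redrawn each repeat with seed
= base seed + repeat index. Both classes are split into five folds whose
sizes differ by at most one. Each fold's test set is its held-out
positives and negatives *plus every remaining unconfirmed pair*, counted
as negatives in the metrics — AUROC and AUPR are therefore measured
against the full candidate universe, which is why AUPR is much smaller
than AUROC at realistic sparsities. Five-fold CV is repeated five times by
default; the reported mean is the mean of per-repeat means and the SD is
the sample SD over the per-repeat means (the alternative — SD over all 25
fold values — is available from the stored per-fold metrics).

**Masking.** By default (`mask_test_positives`) each fold's held-out
associations are zeroed in TDA before that fold's features are computed;
otherwise TDA-dependent features read the test labels directly (fea5's
x = i term literally contains TDA[i,j]).

**Influence coefficients.** For each feature, CV is re-run with that
feature removed under identical folds and negative samples (the
implementation shares the per-fold featurisation across all ten models).
The influence coefficient is the mean of sigmoid(Σ paired AUROC
differences) and sigmoid(Σ paired AUPR differences); the paired sums run
over the 25 fold-level values by default (a repeat-level option exists).
0.5 means no effect; the coefficient is invariant to fold reordering.

**Leave-category-out.** Training positives and sampled negatives exclude
every disease of the investigated category; each category disease with at
least one known association (and not associated with every target) is then
scored against all targets and its AUROC/AUPR computed; the category score
is the mean over those diseases, repeated five times with fresh negatives.
Diseases without a defined AUROC are skipped and counted.

**Case-study rankings.** Leave-disease-out: the investigated disease is
excluded from training entirely, all targets are scored for it over five
repeats with fresh negatives, scores are averaged and the unconfirmed
pairs ranked (ties broken by identifier for reproducibility).
Whole-network: train once on all positives plus sampled negatives, score
and rank every unconfirmed pair.

## Protocol choices in the calibration experiments

Two switches, both off by default to preserve the method's literal
pipeline, are turned on in the package's statistical calibration
experiments (null calibration, signal recovery, ablation comparison in
`scripts/acceptance.py`):

* `recompute_similarity` — the default pipeline computes the GIP layers
  once from the full TDA before CV, mirroring the order
  network-construction-then-evaluation. That order lets held-out
  associations leak into the test features through the similarity layers
  themselves; on synthetic data the leak is strong enough to invert the
  relationship between planted signal and measured AUROC. The strict mode
  recomputes the topological layers and the entropy fusion from the masked
  TDA inside every fold, making the measured AUROC a property of genuine
  generalisation.
* `exclude_self` — with masked test positives but unmasked training
  positives, the self terms let every *training* positive read its own
  label out of TDA while test positives cannot, a train/test shift that
  systematically distorts which features the forest trusts. Excluding the
  query entities from their own neighborhoods and path positions puts
  training and test pairs on the same footing.

In the ablation comparison all ten models additionally share mtry = 3: the
default rule ⌊n/3⌋ would give the eight-feature models mtry = 2, and the
comparison is meant to isolate the removed feature, not a changed
hyperparameter.

## The synthetic generator

The generator plants one latent group structure shared by targets,
diseases and drugs (drugs share it so the co-associated-drug channel of
fea4 is realisable). Entities are assigned to `n_groups` groups uniformly;
each association is an independent Bernoulli draw with probability `p_in`
within a group and `p_out` across, per layer. Semantic similarities are

    s · [same group] + (1 − s) · U(0,1)² + N(0, noise_sd),

clipped to [0, 1], symmetrised by averaging with the transpose (after
clipping), unit diagonal. Two deliberate realism choices:

* the background term is *squared*-uniform, i.e. right-skewed, because
  real ontology- and sequence-derived similarity matrices concentrate most
  pairs at low similarity. A flat background would give semantic rows
  near-maximal entropy, the fusion rule would never select the semantic
  layer, and the signal dial s would be disconnected from the model.
* the association regime is strongly modular (within/between odds ratio
  54), reflecting the modularity of disease–protein associations; the
  per-layer probabilities solve p_in/G + p_out·(G−1)/G = target sparsity
  for the curated-network sparsities 0.007 (TDA), 0.035 (TDI), 0.031
  (DDA) at the default 200×200×200 preset with G = 10 groups.

Disease category labels for leave-category-out testing carry the disease's
own group with probability `category_purity` = 0.7 and a random group
otherwise. Real disease categories cut across similarity neighborhoods;
perfectly group-aligned categories would make leave-category-out remove a
group's entire evidence base, which no method could survive.

What the generator does **not** emulate: degree heterogeneity (hub
diseases), hierarchical or overlapping modules, correlated noise between
the semantic layers, and the ~5× larger entity counts of the curated
network. Passing tests therefore show the pipeline recovers planted
modular structure under realistic sparsity — not that it attains any
particular performance on curated biomedical data.

## Desk-scale experiment sizes

The calibration experiments run on the 200-entity preset with a 150-tree
forest: null calibration over 10 repeats; signal recovery over
s ∈ {0, 0.3, 0.6, 0.9} with 10 generator seeds and one CV repeat each; the
ablation comparison at s = 0.9 over the same 10 seeds with all ten models
sharing folds. Oracle equivalence uses 1000 random 6×6×5 networks. These
sizes give stable means (SE of a mean AUROC ≈ 0.01) with a modest compute
footprint.

## Numerical conventions

* Similarity validation: symmetry to 1e−8, diagonal to 1e−8, range
  [0, 1] with 1e−12 slack; TSV round-trips write 17 significant digits.
* GIP distances are computed from the Gram matrix and symmetrised, the
  diagonal forced to exact 1.
* Entropy ties (equal row entropies) assign the row to the semantic side
  at both partition levels.
* All argmax/ranking ties break to the smallest index / lexicographically
  smallest identifier.
* Negative sampling, fold assignment and label shuffling use
  `numpy.random.default_rng` seeded per repeat; forests use a fixed
  `random_state`, so every protocol is bit-reproducible given its seeds.

## Known limitations

* On single-latent-structure synthetic data the nine features are highly
  redundant (fea5/fea7 and fea6/fea9 are one- and two-hop versions of the
  same evidence; fea1/fea2 are near-global covariates), so single-feature
  ablations move mean AUROC by only ~10⁻³ and a removed feature can tie
  or marginally beat the full model within noise. The universal
  "full set beats every ablation" pattern reported for the curated
  network reflects complementary information channels in real data that
  this generator does not fully reproduce.
* The default pipeline order (similarities before CV) is faithful but
  leaky, as described above; published AUROC values obtained under that
  order should be read accordingly.
* The per-disease AUROC in leave-category-out evaluation is undefined for
  diseases with no (or all) associations; such diseases are skipped,
  which biases category scores toward better-studied diseases.
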