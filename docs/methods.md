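# Methods

## The workflow

`enzrank` implements a few-shot enzyme-prioritization workflow: given a
small set of protein sequences with one real-valued experimental measure
each (typically the catalytic efficiency k_cat/K_M, but any scalar fitness
measure works), it trains a regressor on fixed-size sequence embeddings and
uses it to re-rank a large panel of homologous candidate sequences, so that
wet-lab effort concentrates on the candidates most likely to be highly
active. The stages are:

1. **Labels** (`seqio`): read a FASTA whose header's last whitespace token
   is the measure, or a plain FASTA plus a two-column TSV. Kinetic
   parameters span orders of magnitude, so a `log10` transform of the raw
   values is available (and is the default in the pipeline configuration);
   the transform is applied lazily at training time and all predictions are
   reported in transformed space.
2. **Embeddings** (`embedders`): each sequence becomes one vector by mean
   pooling the per-residue representation rows of one model layer. Any
   backend implementing the three-member `Embedder` protocol (a spec, and
   per-sequence `residues(record, layer)`) can be plugged in — a pretrained
   protein language model adapter fits this contract directly. The package
   ships a deterministic surrogate backend (below) used by all tests,
   examples and the acceptance script.
3. **Regression** (`regression`): three classical families — k-nearest
   neighbors, RBF-kernel support vector regression, random forest — tuned
   by exhaustive grid search over small declared grids, scored by mean
   out-of-fold R² on a seeded 5-fold partition, refit on the full training
   split. Reporting uses Spearman rank correlation (the quantity that
   matters for ranking) alongside R².
4. **Candidate preparation** (`homology`): a precomputed homology-search
   result in BLAST/MMseqs2 tabular (m8) form is filtered to hits with
   E-value strictly below 1e-3 whose alignment spans at least 90% of BOTH
   query and target ("bidirectional coverage"); surviving sequences are
   collapsed at >= 90% pairwise identity by greedy incremental clustering.
   The search itself is out of scope — the package consumes its output.
5. **Ranking and diagnostics**: candidates are sorted by predicted value
   (descending, ties by id) with dense 1-based ranks. The
   `identity_vs_prediction` diagnostic reports the identity-to-query range
   among top-ranked candidates: a wide range indicates the regressor uses
   features beyond mere similarity to the best training enzyme.
6. **Data requirements** (`robustness`): the subsampling protocol draws
   training subsets of increasing size (10 replicates by default per size),
   retrains, and scores each replicate on one fixed held-out 20% split.
   A size is *adequate* when the 95% t-interval of the replicate
   correlations is narrower than 0.1 — and stays narrower at every larger
   sampled size, which guards against noise-induced early crossings. The
   *success rate* is the fraction of replicates with rho strictly above
   0.5. Label imbalance is diagnosed by Fisher's moment coefficient of
   skewness, the unadjusted g1 = m3 / m2^(3/2).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `transform` | `log10` (pipeline), `identity` (API) | label scale before regression |
| `max_evalue` | 1e-3 | hit significance threshold, strict `<` |
| `min_bidir_cov` | 0.9 | alignment span / length on both sides, inclusive `>=` |
| redundancy `threshold` | 0.9 | pairwise identity for clustering, inclusive |
| `train_fraction` | 0.8 | train/test split; train size is round(n · f), half-up |
| `cv_folds` | 5 | grid-search fold count |
| knn grid | k ∈ {1,3,5,7,11,15}, metric ∈ {euclidean, cosine} | |
| svr grid | C ∈ {0.1,1,10,100}, gamma = scale-heuristic × {0.1,1,10}, eps ∈ {0.01,0.1} | |
| rfr grid | trees ∈ {200,500}, max_features ∈ {sqrt, 1/3}, min leaf ∈ {1,3} | |
| `reps` | 10 | subsampling replicates per size |
| `max_ci_width` | 0.1 | adequacy criterion on the 95% CI |

Grids are deliberately small so that an exhaustive search is reproducible
on one CPU in minutes. Ties in grid scores resolve to the first candidate
in deterministic grid order; the random-forest seed controls bootstrap and
feature sampling and is recorded in the trained model.

## Alignment convention

Percent identity is computed from a global Needleman–Wunsch alignment
(BLOSUM62, gap open 11, gap extend 1, end gaps penalized) as identical
columns divided by total alignment columns, gaps counting in the
denominator. Published identities from search tools use their own
conventions, so small deviations (±1 percentage point) from printed values
are expected and tolerated where such values are compared. Identity is
symmetric by construction: the two sequences are ordered canonically before
alignment so both argument orders traverse the same optimal path.

## The surrogate embedder

Tests must demonstrate *signal recovery*, not just plumbing, without
downloading a pretrained model. The surrogate maps residue `i` of a
sequence to a `dim`-vector (default 128) that depends only on the residues
at positions `i-1, i, i+1`, through two channels:

* **composition channel** — one-hot encodings of the residue and of each
  neighbor plus five physicochemical scalars (hydrophobicity, side-chain
  volume, charge, polarity, aromaticity), placed on seeded random signed
  coordinates, scaled by 0.25;
* **locus channel** — the standardized Kyte–Doolittle hydrophobicity of the
  central residue, amplified 4x and written at a coordinate hashed from the
  *neighbor pair*. Along a random reference sequence, neighbor pairs are
  near-unique, so after mean pooling this channel retains locus-resolved
  information.

The locus channel exists because mean pooling annihilates position: the
pooled average of any *linear* function of per-position features is a
function of amino-acid composition alone, so a purely linear per-residue
featurization can never support position-specific fitness prediction. Real
transformer layers are deeply nonlinear in context, which is what the
context-hashed channel emulates in miniature. The channel amplitudes (4.0
vs 0.25) keep the locus signal dominant over composition drift under
pooling.

Layer 0 adds unit Gaussian noise (seeded by sequence content, so calls are
bit-reproducible but noise is independent of record ids); layers 1 and
upward are clean under independent projections. Higher layers are therefore
strictly more informative by construction, which gives the per-layer
cross-validated selection something real to find. Layer selection scores
each layer by mean out-of-fold Spearman rho over a 5-fold partition keyed
to sorted-then-shuffled sequence ids (so the choice is invariant to dataset
order), with full grid-search tuning inside each fold; ties go to the
lowest layer index.

## The synthetic landscape

The generator emulates the statistical shape of a saturation-mutagenesis
training set: a cloud of variants around one random reference (default
length 120) whose observed fitness is

    y = sum_{p in hot} slope_p * hydrophobicity_z(residue_p) + N(0, noise_sd^2)

with 6 hot positions, per-position slopes drawn once from N(0,1), and
noise_sd = 0.3. Mutations are concentrated where the signal is: each hot
position mutates with probability 0.5 per variant, and the background rate
elsewhere is solved so the *mean* per-position rate is 3.5% — giving the
cloud a ~96.5% average identity to the reference, typical of engineered
variant panels. Two design choices matter and were made deliberately:

* **Focused mutations.** Under a uniform 3.5% rate, ~80% of variants carry
  no hot-position mutation at all; their labels are pure noise and even a
  perfect predictor cannot rank them (measured Spearman ceiling ~0.4–0.7).
  Concentrating mutations at hot sites — exactly what a mutagenesis
  campaign targeting an active site does — raises the information ceiling
  above 0.97 so that recovery thresholds test the model, not the generator.
* **Low-rank weights.** If every (position, residue) cell had an
  independent weight, 114 free cells against ~200 training examples would
  make generalization impossible for any regressor. Tying weights to a
  physicochemical property (standardized hydrophobicity) makes the
  landscape additive in a quantity the embedder exposes, so a regressor
  that genuinely learns structure can approach the ceiling and a
  label-permuted null stays near zero.

What the generator does **not** emulate: epistasis, indels, real enzyme
biochemistry, phylogenetic correlation between training and candidate
sequences, and label noise that depends on the measurement magnitude.
Passing recovery tests therefore show that the pipeline extracts additive
local-sequence signal from pooled embeddings at realistic sample sizes —
not that any particular accuracy will be reached on real kinetic data.

## Numerical and procedural choices

* Spearman rho is the Pearson correlation of mid-ranks (ties averaged);
  zero rank variance on either side is an error ("undefined correlation"),
  surfaced as such by the diagnostics that can legitimately encounter it.
* R² is 1 − SS_res/SS_tot about the mean of the true values; constant true
  vectors are an error.
* The confidence interval behind the adequacy rule is the t-interval on the
  replicate mean: width = 2 · t_{0.975, n−1} · sd/√n. Constant replicate
  vectors give width exactly 0.
* Skewness is the unadjusted g1 (population moments), not the
  sample-adjusted G1.
* The 80/20 split uses round-half-up for the train size (159 → 127/32) and
  a seeded permutation; the subsampling protocol draws its fixed test split
  once from the full dataset before any subsampling so curves at different
  sizes are comparable.
* Subsample draws are seeded by (seed, size, replicate), so any single cell
  of the curve can be reproduced in isolation.
* The E-value boundary is strict (a hit at exactly 1e-3 is removed); the
  coverage and identity boundaries are inclusive.
* Greedy clustering visits records sorted by length descending, then id
  ascending, so the longest sequence of a family becomes its
  representative and the outcome is order-independent.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; deterministic backends make pipeline reruns byte-identical.

## Problem sizes used in tests and the acceptance script

Recovery and null checks run on landscapes of n = 250 (5 seeds); learning
curves use n = 280–300 with sizes 20–200 in steps of 20 and 5 replicates
per size with the knn family; filter and clustering checks use 500 planted
hits and 8 planted clusters of 5 members. These sizes were chosen as the
smallest at which the tested effects are stable across seeds.

## Known limitations

* The surrogate embedder is a miniature: it encodes only trigram-local
  information and one physicochemical scale. It validates the workflow's
  statistics, not the representational power of any pretrained model.
* `redundancy_filter` is O(n · k) in pairwise alignments (k =
  representatives found); for panels of many thousands of sequences a
  dedicated clustering tool is the right choice upstream, with this
  implementation as the reference semantics.
* Identity values depend on the alignment convention; printed identities
  from other tools should be compared only to ~1 percentage point.
* The webserver-style pretrained-model adapter is intentionally not bundled
  (no model download at install or test time); the `Embedder` protocol and
  the `embedder.name` config key are the extension point.
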