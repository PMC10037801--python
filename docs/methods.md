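# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `mdapred`, and what the synthetic benchmark does and does
not establish.

## Model and assumptions

The method treats MDA prediction as link prediction on a bipartite graph
whose node attributes come from similarity networks. Its central assumptions
are the standard ones in this literature: functionally similar miRNAs
associate with phenotypically similar diseases; unverified pairs can be
treated as (soft) negatives for training; and the interaction profile of a
node (its row/column of the association matrix) is itself an informative
similarity feature (the GIP kernel).

The pipeline has three learned stages on top of fixed preprocessing:

1. **Multi-order proximity features.** Every similarity view is
   row-normalised and diffused by a K-step random walk with restart; each
   step's transition matrix is converted to a shifted PPMI matrix (log base
   2, negative values clipped to zero). PPMI is invariant to global scaling
   of the transition matrix and zero-preserving; row/column margins are
   taken per step and per view. These features are *not* trainable; all
   learning happens downstream.
2. **Convolutional fusion + structure embedding.** Each of the C_out filters
   spans the complete per-node feature width of every channel and is summed
   across channels — per node, a learned linear functional of its full
   multi-order proximity profile. This is the only kernel geometry that maps
   (C_in, n, n) channels to an n × C_out output without pooling, and it
   keeps the stage linear (no activation is applied after the filter sum).
   The structure embedding concatenates the two first-order views and the
   high-order block in that order.
3. **Attention with neural aggregation and inner-product decoding.** Scores
   are computed only along edges of the (training-fold) association graph;
   LeakyReLU slope 0.2 and ELU for the neighbour nonlinearity follow graph-
   attention convention and are configurable. Self-edges are *not* added to
   the neighbourhood: the node's own representation re-enters through the
   two-branch aggregator, which is the point of that component. Isolated
   nodes receive a zero neighbour representation. Both aggregator branches
   have output width f_tran, so each head contributes 2·f_tran columns and
   the final embedding width is L·2·f_tran.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `n_steps` (K) | 3 | RWR diffusion depth; reference configuration |
| `c_out` | 256 | convolution filters per node type; reference configuration |
| `f_tran` | 256 | transformed feature width per head; reference configuration |
| `n_heads` (L) | 2 | independent attention heads; reference configuration |
| `learning_rate` | 1e-4 | Adam step size; reference configuration |
| `epochs` | 1000 | full-batch epochs; no early stopping, final state returned |
| `alpha` | 0.9 | RWR continuation probability (restart mass 0.1); not pinned down by the reference configuration, so exposed — larger values emphasise multi-hop structure |
| `gamma_prime` | 1.0 | GIP bandwidth scale, the customary default |
| `delta` | 0.5 | semantic depth-decay factor, the customary default |
| `variant` | full | `no_high_order`, `integrated_similarity`, `plain_gat` ablations |

The frequency-based semantic contribution uses the natural logarithm; any
fixed base rescales numerator and denominator of the pairwise similarity
jointly, so the similarities are base-invariant.

## Numerical choices

* All trainable stages, their reverse-mode gradients and the Adam optimiser
  are written directly in NumPy (float64). Gradient correctness is enforced
  by tests comparing analytic gradients with central finite differences
  (observed agreement ~1e-9 relative, asserted at 1e-4).
* Transformation and aggregator weights use Xavier-normal initialisation;
  biases start at zero. Convolution filters also use Xavier-normal over
  their (C_in·n, C_out) shape.
* Predicted probabilities are clamped to [1e-7, 1−1e-7] inside the loss;
  the loss is averaged (not summed) over the training pair set.
* Attention softmax subtracts the per-row maximum before exponentiation;
  rows without neighbours yield zero coefficients and zero aggregate.
* Ranking ties are broken by stable node order; AUTPR@k integrates the
  TPR@k curve over every integer k with a (0,0) anchor, normalised by n so
  the area lies in [0,1].
* A single integer seed drives initialisation and negative sampling; fits,
  fold splits and the data generator are byte-reproducible given the seed.
* Degenerate inputs fail loudly: all-zero similarity rows (row
  normalisation), all-zero profile matrices (GIP bandwidth), single-class
  label vectors (AUC), cyclic disease records, non-finite training loss.

## Cross-validation protocol

Positives and an equal number of once-sampled unknown pairs are shuffled and
split into five parts jointly, so train and test negatives never overlap.
Within a fold, test-positive entries are zeroed before *anything* derived
from the association matrix is computed: the GIP kernels, the
message-passing adjacency and the supervision labels. Semantic and
functional similarities are fold-independent, consistent with recomputing
only the GIP kernels per round. The case-study protocols recompute the GIP
kernels the same way after removing the target disease's pairs.

## The synthetic benchmark

The generator plants `rank` latent blocks assigned round-robin to both node
types. Associations are Bernoulli with probability p_in inside matched
blocks and p_out = 0.02·p_in outside, p_in calibrated so the expected
density matches the spec'd value before label noise; each entry is then
flipped independently with the noise probability. The between/within ratio
is kept at the flip-noise scale so that off-block positives are dominated by
noise, not by structure. Similarity views are the block-membership kernel
(1 within, 0.2 between) plus symmetric Gaussian perturbation (sd 0.05),
clipped to [0,1] with unit diagonal. The DAG forest routes every disease
through block-specific ancestor chains to a shared root, so semantic
similarity computed from the DAGs carries the same block signal.

What this emulates: sparse binary supervision, correlated multi-view
similarities, DAG-derived semantics, and a planted structure whose recovery
is directly checkable. What it does not emulate: the heavy-tailed degree
distribution of real MDA catalogues, name semantics, view-specific biases,
or any graded within-block structure. Passing the benchmark shows the
pipeline can extract a planted low-rank signal without leakage; it does not
certify performance on real HMDD-scale data.

### Information ceiling of the benchmark

Because within-block pairs are exchangeable, no ranker can beat the
Bayes-optimal "matched-block indicator" score on held-out pairs. Simulating
that oracle on the default conditions (nm = nd = 60, rank 4, density 0.1,
noise 0.02, balanced negatives, 5-fold splits) gives a mean AUC of ≈ 0.84;
at 2% flip noise roughly one in eight test positives is an off-block noise
flip that no method can rank. Measured results sit just below this ceiling:
the first-order-only variant reaches ≈ 0.83 mean AUC and the full model
≈ 0.79 (3 seeds × 5 folds, C_out = f_tran = 32, 300 epochs). The gap between
the two is a small-sample effect: the first-order views alone already
saturate the ceiling here, while the high-order pathway adds capacity that
memorises the ~900 training pairs (training AUC reaches 1.0 well before 300
epochs). On data whose first-order views are weaker than the planted-block
kernel — the regime the method targets — the high-order pathway is the
component that contributes global structure.

## Known limitations

* Dense in-memory linear algebra throughout; intended for nm, nd up to a
  few thousand, not genome-scale graphs.
* Full-batch training only; no early stopping, dropout or weight decay, so
  on very small datasets the final-epoch state can be past its best
  held-out performance (see the ceiling discussion above).
* The disease-DAG dialect is a deliberately simple edge-list stand-in for
  MeSH descriptor trees; no ontology normalisation is attempted.
* Unverified pairs are treated as negatives when sampled, a standard but
  knowingly imperfect assumption of the field.
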