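# Methods

## Problem and model

The package scores every disease–miRNA pair for association, starting
from a binary association matrix `A` (rows diseases, columns miRNAs),
disease ontology DAGs, and per-miRNA disease-term annotation sets. The
method composes four stages; all numerical work is dense double
precision, and prediction contains no randomness at all (seeds only
affect cross-validation fold assignment and synthetic data).

### Similarity layers

*Disease semantic similarity* follows the Wang construction on ancestor
closures: the contribution of ancestor `t` to disease `d` is 1 at `d`
itself and decays by `delta_sem` per generation through the best child
inside the closure (`D_d(t) = delta_sem · max D_d(t′)`). Two diseases
are similar in proportion to the contribution mass of their shared
ancestors. The base case `D_d(d)=1` is the standard convention: a
contribution is a number, and the whole-DAG total is anchored by it.
A disease present in the analysis but lacking a DAG gets an all-zero
off-diagonal semantic row (self-similarity stays 1); those holes are
what the integration step exists to fill.

*miRNA functional similarity* is the best-match average: with term sets
`DTT_i` (size k) and `DTT_j` (size l),
`MFS = (Σ_m maxSS(d_im, DTT_j) + Σ_n maxSS(d_jn, DTT_i)) / (k+l)`.
An empty term set is an error, not a silent zero — silent zeros corrupt
the average. A term absent from the semantic matrix's vocabulary is
likewise an error.

*GIP kernels* use profiles taken from the **binary** matrix by default
(the workflow computes kernels before the completion step; a caller can
pass the completed matrix explicitly to probe the alternative). The
bandwidth `gamma = gamma_prime / mean squared profile norm` with
`gamma_prime = 1`; an all-zero matrix leaves the bandwidth undefined and
is rejected.

*Integration* keeps the semantic/functional value wherever one exists
and falls back to the kernel. "Exists" defaults to the elementwise test
`primary > 0`, which covers both genuinely-zero similarity pairs and
whole no-DAG rows; an explicit boolean mask argument supports the
per-entity reading instead. The diagonal is forced to 1 to guard float
drift.

### WKNKN completion

For each disease, the K most similar *known* diseases (at least one
association in the matrix being completed, self excluded, ties broken by
label) contribute their profiles with weights `r^{t−1}·sim`, normalized
by the sum of the K similarities; the miRNA side is symmetric; a zero
estimate is used when no known neighbor or all-zero similarities exist
(no information, no division by zero). The completed entry is
`min(1, (Yd+Ym)/2)` for zeros and exactly 1 for known positives — the
clip is a guard, since weighted averages of binary profiles cannot
exceed 1. Neighbor search uses the integrated similarities by default;
passing `DSS`/`MFS` directly probes the primary-only alternative.
Because "known" is judged on the matrix being completed,
cross-validation folds re-run the completion on their masked matrices.

Defaults `K=5`, `r=0.7`: the number of borrowed neighbors balances
filling the sparsity against re-introducing imbalance, and the decay
discounts weaker neighbors; these are the method's standard operating
values and both are exposed.

### Heterogeneous networks

`disease_base = ISD·A_new` and `mirna_base = A_new·ISM` weight each
association edge by how much the rest of one space resembles its
endpoint. The inter-space transition from disease `i` distributes total
mass `phi` over miRNAs proportionally to `A_new ∘ mirna_base` row `i`;
the miRNA-to-disease transition distributes `phi` down each column of
`A_new ∘ disease_base`. Rows/columns with zero denominator stay zero:
after completion these are rare, and the restart term keeps the walk
well defined. Intra-space rows are similarity rows normalized by their
row sum *including* the unit diagonal (self-loops are kept, per the
literal construction), scaled by `1−phi` only for entities that have at
least one association — an isolated entity has nowhere to jump, so its
full mass stays inside its own space.

Both networks stack as `[[Wd, T], [Tᵀ, Wm]]` with `T` the n_d×n_m
inter-block (row-normalized `T_DM` for the disease-based network,
column-normalized `T_MD` for the miRNA-based one); this is the only
dimensionally consistent placement of the blocks. Consequently the
disease rows of the disease-based network sum to exactly 1 (`(1−phi) +
phi`) whenever their inter denominator is nonzero, while the opposite
space's rows are *not* renormalized — the construction is kept verbatim
rather than forced row-stochastic, and the restart iteration below is a
contraction regardless.

### Random walk with restart and fusion

The state is a full `(n_d+n_m)²` matrix seeded block-diagonally:
disease seeds carry `(1−delta)/n_d`, miRNA seeds `delta/n_m`, trace 1.
The recurrence `P_{t+1} = (1−gamma)·W·P_t + gamma·P_0` left-multiplies
by the assembled network (propagation along columns; the convention is
fixed here and mirrored by the series oracle in the tests). Iteration
runs a fixed `t_max = 10` steps by default; an optional tolerance stops
earlier on `max|ΔP| < tol`. Ten steps suffice because the update is a
contraction with factor `(1−gamma)·‖W‖`; at `gamma=0.7` the tail beyond
step 10 is bounded by `0.3^10 ≈ 6·10⁻⁶` times the state scale, and the
test suite verifies the 10- vs 50-step gap is below 10⁻⁶ on the default
study size.

The two walks are fused as `P = (1−delta)·P1 + delta·P2` — the same
`delta` weights the seeding and the fusion, one parameter for one
concept of sub-network importance — and scores are read from the
disease×miRNA off-diagonal block averaged with the transpose of its
mirror (a flag selects the top-right block alone). No per-column
normalization is applied to `P1`/`P2` before fusing.

Defaults `phi=0.9`, `delta=0.7`, `gamma=0.7` are the method's standard
operating combination.

## Evaluation protocol

AUC comes from an explicit threshold sweep with tie grouping (trapezoid
rule; exactly the Wilcoxon–Mann–Whitney statistic with midranks), AUPR
from the conservative rectangular recall-step rule anchored at recall 0
with the first attainable precision. Both are implemented in the
package; scikit-learn serves only as an independent cross-check in the
tests.

Five-fold cross-validation partitions **all** `n_d·n_m` pairs —
positives and negatives together — into folds; per fold the test
positives are zeroed in training, kernels and completion are recomputed
from the masked matrix, and metrics are taken over the held-out pairs
(held-out positives vs held-out unknown pairs; training positives never
enter the negative pool). Folds whose test pairs are single-class are
skipped with a warning and recorded. Per-fold means and pooled (scores
concatenated across folds) values are both reported, since either
aggregation is defensible. Global LOOCV masks each known pair in turn
and rescores it with a full pipeline re-run; never-known pairs are
scored once by the full-data model. Evaluation labels are the original
binary associations; comparing against the completed matrix binarized
at a threshold is possible by the caller but is not the default,
because the completion is part of the model under test.

## Synthetic studies

The generator emulates the three external inputs with a planted
co-cluster structure: `n_blocks` aligned disease/miRNA blocks (default
4 on 60×80), within-block association density 0.3 versus background
0.01 — matching the order of sparsity of curated association catalogs
while leaving enough signal for a desk-scale study — an ontology forest
with one rooted tree per disease block (depth 3) so semantic similarity
mirrors the planted blocks, and per-miRNA term sets subsampled (1–5
terms) from each miRNA's planted associations. All-zero rows/columns
are repaired with one forced within-block positive so every entity is
observable. One integer seed drives each fixture; regeneration is
byte-identical.

What the fixtures do **not** emulate: real MeSH DAGs are deeper,
diamond-shaped and share ancestors across branches (diamonds are
exercised by unit tests, not the generator); real association catalogs
have heavy-tailed degree distributions rather than homogeneous blocks;
and disease/miRNA similarity structure in nature is not perfectly
aligned with association structure. Passing the planted-signal tests
therefore demonstrates correct mechanics and sensible ranking behavior
under a known ground truth, not clinical-scale accuracy figures.

## Numerical choices and edge cases

- Ties in every ranking and neighbor selection break by score/similarity
  descending, then label ascending — deterministic without positional
  assumptions.
- Labelled TSV round trips serialize floats with 17 significant digits
  (bit-stable for float64); parsers report the offending line/column.
- Symmetry of similarity matrices is enforced to 1e-12 at construction;
  computed layers are exactly symmetrized and their diagonals pinned
  to 1.
- Zero normalizers (WKNKN neighbor sums, inter-transition denominators,
  all-zero similarity rows) yield zero contributions, never errors;
  the only hard input errors are an all-zero association matrix (GIP
  bandwidth undefined), empty annotation sets, vocabulary mismatches,
  and cyclic ontology edges.
- Non-finite values during propagation abort with the iteration number.

## Known limitations

- The walk state is a dense `(n_d+n_m)²` matrix; fine to a few thousand
  entities, not beyond.
- Leave-one-out re-runs the full pipeline once per known association;
  on large catalogs prefer the five-fold protocol.
- `K` and `r` are not learned; the defaults are operating points, and
  sweeping them is the caller's job.
- Diseases with no DAG *and* no associations in a training fold are
  effectively invisible to that fold's model.
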