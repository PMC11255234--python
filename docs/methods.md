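# Methods

## Problem and model

The package predicts human odor descriptors ("fruity", "sulfurous", ...) from
molecular structure — a multilabel classification over a skewed descriptor
vocabulary, where most descriptors are rare and a molecule typically carries a
handful. Its core is a graph network that replaces the conventional
bond-adjacency graph with the Coulomb matrix (CM),

    C_ii = 0.5 Z_i^2.4,     C_ij = Z_i Z_j / |R_i - R_j|  (i != j),

computed over all nuclei (explicit hydrogens included) with distances in
angstroms as supplied by the conformer. The CM is a fully connected weighted
graph: every atom pair has a direct edge, which removes the long-path
bottlenecks (oversquashing) of sparse bond graphs and carries 3D and
electrostatic information the adjacency matrix cannot. Because raw entries
span orders of magnitude (a sulfur diagonal is ~389 vs ~37 for carbon), one
matrix-wise normalization is applied before message passing: division by the
Frobenius norm (default) or min–max scaling, each guarded by eps = 1e-9.

Atom embeddings are updated by residual graph convolutions

    H_l = SELU(X H_{l-1} W_graph) + H_{l-1} W_linear,

sum-pooled into a molecule embedding m, and mapped to per-descriptor
probabilities by a logistic layer. The two sigma symbols in the architecture
are resolved deliberately: the convolution nonlinearity is SELU, while the
classification head is the logistic function, because the loss below needs
strict probabilities in (0, 1).

The full model additionally replaces the initial per-element atom embedding
with a learned positional encoding (LPE): for each atom, the p lowest
(eigenvalue, eigenvector-component) pairs of a CM graph Laplacian form a
p x 2 input, which is linearly lifted to width d, processed by a small
Transformer encoder as a length-p sequence, and sum-pooled into that atom's
initial embedding. Degrees are off-diagonal row sums (zeroing the CM diagonal
first, which provably leaves the combinatorial and symmetric Laplacians
unchanged); the "asymmetric" variant is the random-walk Laplacian
I - D^{-1}X, solved through its similarity-equivalent symmetric problem so the
spectrum stays real. Four presets share one code path: `adjacency_gcn`,
`coulomb_gcn` (per-element initial embeddings), and `lpe_sym` / `lpe_asym`
(LPE initial embeddings from the symmetric / random-walk Laplacian).

The loss couples binary cross-entropy with a logarithmic regularization term
per descriptor,

    l_i = BCE(y_i, p_i) + |log(y_i + eps) - log(p_i + eps)|,
    l   = (1/o) sum_i w_i l_i,     w_i = 1 - n_pos_i / n_tot,

averaged over the batch. The weights down-weight frequent descriptors; the
log term is strongly asymmetric, punishing large probabilities on negatives
far harder than BCE alone. eps = 1e-9 everywhere (the same guard as the
normalizations).

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| p | 20 | spectral rows per atom (lowest eigenpairs, zero-padded when n < p) |
| d | 32 | embedding width (h = d hidden width) |
| GCN depth | 3 | residual convolution layers |
| LPE Transformer | 1 layer, 4 heads, feed-forward 2d | post-norm encoder |
| normalization | frobenius | CM scaling for message passing |
| learning rate | 1e-3 (Adam) | batch 32, up to 300 epochs, patience 20 on validation macro-AUROC |
| threshold | 0.5 | decision threshold for confusion-matrix metrics |
| min_count | 30 | minimum molecules per retained descriptor |
| split | 0.8/0.1/0.1 | second-order iterative stratification |

p and d follow the reference architecture; depth, widths, optimizer and
threshold are not dictated by it and are exposed in `ModelConfig` /
`TrainConfig`. Biases are included by default with a `bias=False` switch for
the literal bias-free algebra used in equivalence tests.

## Design choices that were genuinely open

- **Hydrogens** are part of the atom list: the CM is defined over nuclei, and
  the reference CM literature includes them. Configurable off.
- **Conflict rule**: a molecule labeled both "odorless" and odorant keeps the
  odorant descriptors; the resolution is logged per molecule.
- **Merge key** for duplicate records: canonical SMILES of the largest
  (de-salted) fragment.
- **Conformers**: ETKDG embedding with a fixed seed plus MMFF94 relaxation;
  SDF-supplied coordinates take priority and are never regenerated.
- **Trivial eigenpair**: the near-zero lowest eigenpair is kept among the p
  lowest (`drop_trivial_eigenpair` removes it). Eigenvector signs are
  canonicalized — the largest-magnitude component is made positive, ties
  resolved by lowest atom index — so decompositions are deterministic rather
  than augmented by random sign flips. Degenerate eigenspaces are kept in the
  solver's stable order; no within-eigenspace rotation is attempted (a known
  limitation).
- **Initial embedding of the LPE model**: the `lpe_sym` / `lpe_asym` presets
  combine the positional encoding with a learnable per-element embedding
  table (`combine_atom_embedding`, switchable off for the purely spectral
  variant). The Laplacian eigenpairs encode geometry but carry element
  identity only indirectly through edge weights; on element-determined
  labels the purely spectral initialization learns markedly slower, which
  motivated the combined default. Scale matters: the LPE pooled output grows
  like sqrt(p), so the element table is initialized at that magnitude —
  at the conventional 1/sqrt(d) scale the positional signal drowns the
  element signal and the combination behaves no better than LPE alone.
- **Head initialization**: because sum-pooling scales logits with atom count,
  the classifier weights start at 1/100 of Glorot scale so initial
  probabilities are not saturated; the loss additionally clamps probabilities
  at 1e-12 against float rounding.
- **Batching** pads molecules to a common size with atom masks; masked atoms
  contribute exactly zero to messages and pools (tested).
- **Second-order iterative stratification** assigns samples
  rarest-label-combination first, each to the split with the greatest
  remaining demand for that combination, ties broken by remaining capacity
  then split index; label-pair combinations (order 2) are balanced alongside
  single labels.

The network and its gradients are implemented on a small reverse-mode
autodiff engine over NumPy float64 (`odorgraph.autodiff`); gradient
correctness is pinned by central-difference checks in the test suite.

## Synthetic fixtures

The generator (`odorgraph.synthetic`) builds valence-correct random skeletons
over {C, N, O, S, Cl} (4–18 heavy atoms, optional single ring), adds
hydrogens and ETKDG/MMFF coordinates, and labels them with three structural
predicates — sulfur presence, chlorine presence, and compactness (heavy-atom
diameter < 7 A) — plus 5% independent label flips. The standard fixture is
200 molecules with seed 0. The compactness rule is deliberately
conformer-dependent so that Coulomb-based models can exploit 3D information
that bond adjacency cannot see; the flip noise emulates annotator
inconsistency. What the fixture does **not** emulate: real odor semantics,
descriptor co-occurrence structure, tautomers/stereochemistry, and the
~8.5k-molecule scale of curated odor datasets — passing tests demonstrate
that the pipeline learns structure-determined labels at desk scale, not that
it reproduces published benchmark scores.

## Problem sizes used in tests and the acceptance script

Training runs in the shipped tests and in `scripts/acceptance.py` use the
standard 200-molecule fixture with batch size 16 and at most 150 epochs
(patience 30; convergence is typically reached near epoch 60); label-shuffled
controls train 30 epochs (chance level does not move with more); the
representation-ordering comparison trains the two fast per-element-embedding
configurations across several training seeds (three in the tests, five in the
acceptance script). The standard fixture comprises both the generated
molecules (seed 0) and their stratified partition (split seed 0), so every
run compares models on the same held-out evaluation set; run seeds control
initialization and training stochasticity only.
Held-out evaluation pools the validation and test splits (40 molecules)
against the noise-free predicate labels, which measures recovery of the
structural rules rather than the injected noise.

## Known limitations

- The Laplacian eigenbasis is ambiguous under eigenvalue degeneracy; only
  sign ambiguity is canonicalized.
- Conformer generation yields one low-energy conformer; conformational
  ensembles are out of scope.
- With `combine_atom_embedding=False` the initial embedding carries no
  explicit element identity; element information then reaches the network
  only through CM edge weights, which slows learning of purely
  element-determined labels.
- Micro-averaged metrics are available but the headline numbers are
  macro-averages over descriptors with at least one positive and one negative
  in the evaluated slice.
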