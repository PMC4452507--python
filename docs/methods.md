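# Methods

## Model

The package scores drug–disease pairs with a sigmoid-output matrix
factorization whose factor matrices are initialized from network-derived
feature vectors ("warm start"). The modeling assumptions, in order of
load-bearing:

1. **Associations have molecular evidence.** If a drug treats a disease,
   the drug's target genes and the disease's genes are assumed to lie close
   to each other in the gene interaction network. This is what makes the
   genomic space informative at all.
2. **Closeness decays exponentially with hop distance.** The kernel
   `c = a'·exp(−b'·d)` with defaults `a' = 10`, `b' = 0.25` maps hop counts
   to a bounded similarity; unreachable pairs get closeness 0 (the limit of
   the kernel, keeping the relation matrix finite). The scale is a benign
   monotone transform; results depend on it only through the training
   dynamics.
3. **Low-rank structure suffices.** The relation matrix is truncated to its
   top-k eigenpairs (`k = 32` by default). The exponential shortest-path
   kernel is not guaranteed positive semidefinite, so the decomposition
   requires the retained eigenvalues to be strictly positive and fails
   loudly otherwise (square roots of negative eigenvalues are undefined);
   in practice the top tens of eigenvalues of these kernels are
   comfortably positive.
4. **Entity vectors are interactor means.** A drug/disease vector is the
   arithmetic mean of its interacting genes' vectors — each entity lies in
   the convex hull of its genes. Entities with no interactors get i.i.d.
   Uniform(−0.1, 0.1) vectors (seeded); the small symmetric scale keeps
   their initial scores near 0.5 and the training reported here is
   insensitive to the exact scheme.

## Training

Stochastic gradient descent on the L2-regularized squared loss, one shuffled
pass over the labeled pairs per epoch (shuffle order seeded). Per sample,
both rows are updated *simultaneously* (the disease update uses the
pre-update drug row), matching the gradient of the loss at the current
point. The regularization term accrues once per sample visit, so rows
occurring in many pairs experience proportionally more weight decay — this
is the literal reading of the per-pair loss and its update rule, and it has
a visible consequence discussed under Limitations.

Numerical choices:

- dot products are clipped to ±30 before exponentiation (sigmoid is exact
  to double precision beyond that; no effect at default scales);
- convergence is declared when the relative change of the full objective
  between epochs drops below `tol = 1e-5`, with a hard cap of 500 epochs —
  at the corpus sizes used here the cap usually binds, and the entire loss
  trace is returned for auditing;
- a non-finite loss aborts with the offending epoch (divergence guard);
- eigenvector signs are fixed (largest-magnitude component positive) so
  embeddings are reproducible; predictions are invariant to this choice;
- tied eigenvalues keep the solver's ordering after the descending sort;
  exactly degenerate spectra are only meaningful through `P·Pᵀ`, which is
  well defined.

The SGD inner loop is jitted with numba (a pure-Python fallback computes
identical IEEE sequences), so a full 5×10-fold comparison at corpus scale
runs in seconds.

## Evaluation protocol

- **Negative sampling.** 2 negatives per positive, drawn uniformly without
  replacement from the non-positive cells of the drug × disease grid, once
  per repeat, so all folds of a repeat share one sample universe.
- **Folds.** `pair`: samples shuffled into 10 near-equal folds. `drug` /
  `disease`: the *entities* are partitioned; a fold's test set is every
  sample touching its entities, so test entities have no training pairs
  (asserted by tests). Cold entities are scored purely from their
  warm-start rows (full) or random rows (mf).
- **Feature extraction happens once, outside the folds.** Features depend
  only on the genomic space, never on association labels, so there is no
  label leakage.
- **Paired mode comparison.** All modes of a comparison run on identical
  negatives and folds (shared per-repeat seeds); mode differences are
  therefore assessed on per-repeat paired differences, which removes the
  (large) negative-sampling variance component.
- **AUC** is the Mann–Whitney statistic (ties ½), computed by
  scikit-learn; tests cross-check it against exhaustive pair counting.

## Synthetic data generator

The generator emulates the structure of a small curated repositioning
corpus: a scale-free gene network of 1000 genes / ~4000 edges (preferential
attachment, matching the interactome's mean degree of ~8), 130 drugs with
2–10 target genes clustered in network neighborhoods, 50 diseases with 1–2
genes, and 213 positive associations. Three structural features are modeled
deliberately:

- **Planted proximity signal.** A pair's selection weight is proportional
  to the mean pairwise closeness between the drug's and the disease's gene
  sets, computed with a sharper decay (`b' = 2.0`) than the analysis kernel:
  a 1000-node scale-free graph is small-world (most gene pairs sit 2–4 hops
  apart), and under the gentle analysis decay the closeness of gene sets
  varies by only ~12%, too flat to carry a signal.
- **Drug-side centrality correction.** The weight divides each drug's
  closeness by its mean closeness over all diseases: what is meaningful for
  a multi-gene target set is proximity to *this* disease relative to its
  baseline proximity to everything. Raw feature dot products track absolute
  closeness and therefore rank such data only moderately well, while the
  feature geometry still carries the signal — precisely the regime in which
  initialization (not direct similarity) is the right way to use the
  genomic space. The disease side (1–2 genes, little centrality spread) is
  left uncorrected.
- **Hub propensities.** Independent lognormal per-entity factors (sd 0.5
  for drugs, 1.5 for diseases, matching the corpus asymmetry of ~1.6
  indications per drug vs ~4.3 drugs per disease) multiply the weight.
  Training can learn hubs from labels alone; feature dot products cannot.

The structured weight is mixed with the uniform distribution:
`signal_strength` (default 0.9) is the probability mass on the structured
part, and `signal_strength = 0` yields exactly uniform positives (the null
control). Positives are drawn without replacement.

**What the generator does not model:** realistic biological topology beyond
the degree distribution; correlated drug target families; disease gene
modules shared across related diseases; noise in the interaction data
itself. Passing the synthetic study therefore shows that the pipeline
recovers a proximity-plus-popularity signal planted at corpus scale — not
that any particular real corpus carries such a signal.

## Problem sizes

The test suite runs the full corpus-shaped study (1000 genes / 130 drugs /
50 diseases / 213 positives, 5×10-fold CV) for the mode-ordering and
cold-start checks, three such datasets for the null control, and smaller
configurations (hundreds of genes, tens of entities) for unit and CLI
tests. The acceptance script repeats the full study from a command-line
seed in about half a minute.

Because a single draw of 213 uniform positives carries ~0.025 of AUC
sampling noise, the null control averages each mode over three
independently generated null datasets.

## Limitations

- **Per-visit weight decay distorts popularity transfer.** Since
  regularization is applied at every sample visit, rows of frequently
  sampled entities decay more per epoch. At 500 epochs this measurably
  anti-correlates a drug row's generic component with its training-pair
  count, which weakens cold-start transfer of popularity.
- **Disease cold-start is near chance.** With 1–2 genes per disease, a
  cold disease's warm row carries little geometry beyond its norm, and the
  warm-started model's advantage over random initialization in the disease
  setting is a near-tie at these sizes (it can land on either side of the
  random-initialization baseline depending on the dataset draw). Drug
  cold-start, with 2–10 genes per drug, shows a large and stable advantage.
- The convergence cap (500 epochs) usually binds before the relative-change
  criterion; longer training slowly overfits the sampled negatives.
- All IDs are opaque strings; nothing is validated against DrugBank, OMIM
  or Entrez.
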