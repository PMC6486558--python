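# Methods

## The model

`cellpresence` treats single-cell type assignment as supervised
classification over binarized expression. A cell's UMI count vector is
reduced to presence/absence calls (any positive count → 1) on a fixed,
ordered reference gene space; the binary vector feeds a fully connected
network

    input (|gene space|) → dense 200, ReLU → dropout 0.4
                         → dense 100, ReLU → dropout 0.4
                         → dense K+1, softmax

whose outputs are the K known cell types of a catalog plus a terminal,
explicit **Unknown** class. Binarization is the modeling commitment, not a
preprocessing shortcut: digital UMI counts make a single detected molecule
evidence of expression, presence of signature genes carries most of the
type information (as in flow cytometry), and dropping magnitudes makes the
classifier robust across platforms and sequencing depths without
normalization, log transforms or highly-variable-gene selection. Technical
dropouts are tolerated the way dead pixels are tolerated in image
recognition.

Training minimizes class-weighted categorical cross-entropy by mini-batch
SGD (batch 1024, learning rate 0.01, momentum 0.9). Per-sample weights are
the balanced inverse-frequency class weights
`w_c = N / (C_present · N_c)`, which satisfy `Σ_c w_c N_c = N` exactly and
keep rare cell types from being drowned out. A stratified 20% of the
training cells is held out for validation; training stops when validation
loss fails to improve for `patience` (default 3) epochs and the best-epoch
weights are restored. Dropout is active only inside the mini-batch update.
Learning rate, momentum and the fan-in-scaled uniform weight
initialization are package choices exposed in the configuration; with a
fixed seed and one CPU thread every training run is bit-reproducible
(splits, shuffles and dropout masks all derive from one seed sequence).

The Unknown class is trained on *synthetic unknown* profiles: real cell
profiles whose gene values are permuted uniformly within the cell. The
permutation preserves the number of detected genes (library complexity)
while destroying all co-expression structure, so the profile resembles no
real type. Shuffling within-cell across genes (rather than within-gene
across cells) is the implemented reading; it is the variant that preserves
per-cell complexity.

## Continual-learning upgrades

Two upgrade protocols continue from the current parameters rather than
retraining:

* **Online update** (same catalog): ordinary SGD on the new data. Because
  new datasets typically cover a biased subset of the catalog, naive
  updating causes catastrophic forgetting of the absent types. The *review
  training* mechanism replays a fresh random sample (default 4000 cells,
  without replacement within an epoch) of the retained previous training
  pool after each epoch on the new data — replay happens as a single pass
  after the epoch, not mixed into every mini-batch. The pool is stored in
  the model archive; if absent, review is skipped with a warning.
* **Catalog expansion** (new types): the output layer is widened — existing
  class columns copied, new-type columns freshly initialized with the
  init-time scheme and zero bias, new types inserted before the terminal
  Unknown — and the **first hidden layer is frozen** so its learned feature
  transform is reused bit-exactly; the second hidden layer and output layer
  train on the new-type data with review training as above. The version tag
  increments (v1 → v2) on expansion. Online updates train all layers;
  freezing is an expansion-only device.

## Signature genes by information gain

For each (type, gene) pair a 2×2 contingency table tallies (in-type vs
rest) × (present vs absent), and the gene is scored by

    Gain(T;G) = H(T) − Σ_{j∈{present,absent}} P(G=j) · H(T | G=j)

with binary one-vs-rest type membership T, base-2 logarithms (bits) and
0·log 0 := 0. For binary T and G this equals the mutual information
I(T;G) = H(T) + H(G) − H(T,G), which the test suite uses as an independent
brute-force oracle (agreement to 1e−12). The per-type one-vs-rest
decomposition is the implemented form because a single 2×2 table then
suffices; the ranking is invariant to the logarithm base, gains are clipped
at zero against rounding, and ties break lexicographically by gene symbol
for determinism. The default report is the top 50 genes per type.

## Gene-space alignment

Input matrices are projected onto the model's reference gene space before
binarization: symbols are uppercased and stripped, optionally translated
through a user-supplied homolog map (e.g., mouse→human symbol pairs), genes
absent from the reference are dropped, reference genes absent from the data
become all-zero rows, and duplicates collapsing onto one reference symbol
merge by element-wise maximum (presence-preserving). If fewer than 20% (configurable)
of the reference genes are found, alignment fails hard — the typical
signature of a wrong species or annotation build. The reference space
itself (the original work used a 16,013-gene human–mouse homolog list) is
user-supplied configuration; any ordered unique symbol list is accepted.

## The synthetic generator

Real annotated atlases are external resources with hand-curated label
mappings; the package instead ships a generator whose defaults define the
study conditions for all tests:

| parameter | default | meaning |
|---|---|---|
| `n_types` | 6 | cell types |
| `markers_per_type` | 40 | marker genes owned by each type |
| `n_background_genes` | 1500 | uninformative genes |
| `p_marker_on` | 0.8 | marker presence in its own type |
| `p_marker_off` | 0.05 | marker presence elsewhere |
| `p_background_on` | 0.10 | background presence |
| `cells_per_type` | 500 | balanced class size |
| `dropout_extra` | 0.1 | global extra zeroing of presence calls |

Genes are independent Bernoulli draws given the type. The generator
emulates the feature structure the classifier assumes — sparse binary
profiles with type-specific marker blocks and technical dropout — but not
gene–gene correlation beyond type identity, count depth variation, doublets
or batch structure (beyond an explicit presence-probability offset knob).
Passing tests therefore demonstrate the correctness of the machinery and
its behaviour under the assumed signal model, not performance on real
atlases.

Two benchmarks are derived from it. The *upgrade benchmark* draws marker
blocks for extra types into the shared gene space; those cells are labeled
Unknown in phase 1 and specifically in phase 2, mirroring a catalog
expansion. The *domain-shift benchmark* reobserves the same catalog with
every presence probability shifted (+0.45 by default, a deep/noisy regime
in which foreign markers fire often) and restricted to half the types —
updating on such data actively relabels patterns resembling the old types,
which induces measurable forgetting; review training counters it.

## Problem sizes and numerical choices

The shipped experiments run at the generator defaults (3000 training cells,
1740 genes) for classifier recovery, the forgetting and expansion
benchmarks, and 5-fold cross-validation; unit tests use a reduced-scale
study (4 types × 15 markers, 260 genes, 120 cells/type) with the mini-batch
size scaled down to 128 so an epoch still contains several updates. The
forgetting comparison runs both arms for a fixed 40 epochs (patience
disabled) so the review and no-review conditions see identical optimization
budgets; expansion training runs up to 50 epochs with patience 10, since
only two layers are trainable. The review sample is 2000 cells per epoch
there, scaled to the 3000–3500-cell retained pools (the 4000-cell default
presumes an atlas-scale pool). Softmax is computed with max-subtraction;
predicted probabilities are exact ties only in degenerate cases, which
argmax resolves toward the lowest catalog index.

## Known limitations

* Binarization discards magnitude; types distinguished mainly by expression
  level rather than gene identity are outside the signal model.
* No rejection threshold on probabilities: a cell of a truly novel type is
  assigned Unknown only insofar as the Unknown class has learned to absorb
  implausible profiles; confidence calibration is not attempted.
* The replay pool grows with each upgrade (old pool + new data); no
  reservoir subsampling is applied.
* Homolog mapping is taken as given; many-to-many ambiguities are resolved
  by the element-wise-maximum collapse, not by orthology inference.
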