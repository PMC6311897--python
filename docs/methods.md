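# Methods

This note documents the models and procedures implemented in `scfp`, the
choices made where the design was genuinely open, and what the bundled
synthetic benchmark can and cannot show.

## Input representation

A molecule is normalized to a single canonical SMILES string in Kekulé
form (uppercase atoms, explicit double bonds). Kekulé form is used because
the symbol inventory of the feature matrix has no lowercase aromatic-atom
entries: aromaticity is an *atom feature*, not a token. Canonicalization
and all atom-property perception use RDKit; the i-th ATOM token is aligned
to the i-th atom emitted by RDKit's canonical SMILES writer, which
guarantees token/atom correspondence.

Tokenization maps each canonical-SMILES symbol to one matrix row:

- ATOM tokens: element symbols, including two-letter elements (`Cl`, `Br`,
  bracket-atom elements) as single tokens. Bracket-attached hydrogens and
  isotope digits are folded into the atom token (H counts are re-derived
  from RDKit perception, never parsed from text; isotopes carry no
  feature). When a chirality mark sits between the atom symbol and its H
  count (`[C@H]`), the H text rides on the chirality token so that token
  texts always concatenate to the exact canonical string.
- GRAMMAR tokens: the 21 structural classes — `(`, `)`, `[`, `]`, `.`,
  `:`, `=`, `#`, `\`, `/`, chirality (`@` and `@@` share one class; the
  R/S distinction lives in the atom block), `+`, `-`, ion-charge digits
  2–7, ring-start and ring-end. Ring-closure digits (including `%nn`)
  are classed by a per-label open/close matching rule; labels are
  reusable after closing. Repeated charge signs (`++`) are normalized to
  sign + magnitude before tokenization.

Each token becomes a 42-vector: 21 atom descriptors (type one-hot over
{H, C, O, N, other}; H count; degree; formal charge; total valence; ring
flag; aromatic flag; CIP chirality one-hot over {R, S, other};
hybridization one-hot over {s, sp, sp², sp³, sp³d, sp³d², other}) or one
of 21 grammar one-hot bits. Counting features are stored as raw integers;
an optional standardization is *not* applied by default — the network
consumes raw values. "Degree" is RDKit's connectivity degree (number of
bonded heavy neighbours), the quantity the toolkit actually reports,
although descriptions of this feature sometimes read "degree of
unsaturation". Matrices are zero-padded to `max_len` rows (default 400, a
dataset-maximum choice; any length ≥ the longest tokenized input works).

## Network

Two convolution + pooling stages along the string, then global max
pooling, one hidden layer, and a sigmoid output:

| stage | default |
|---|---|
| conv1 | 128 filters, window k₁ = 7, stride 1, kernels span all 42 columns |
| pool1 | average, window 7, stride 1 |
| conv2 | 64 filters (= SCFP dimension), window k₂ = 7, stride 1 |
| pool2 | none |
| global pool | max over sequence positions |
| head | 96 hidden units, sigmoid output |
| activation | LeakyReLU (slope 0.2); ReLU and PReLU available |

The searchable family also admits max pooling, batch normalization after
convolutions, dropout before the output, windows in [1, 51], strides in
{1, 3, 5} and "half" zero-padding; all are implemented and validated by a
numerical gradient check, but defaults keep them off. The defaults above
were fixed once — windows of 7 with stride 1 and a width-7 average pool —
so that the motif-size bound below evaluates to 21 symbols; they are not
tuned per dataset.

Training is mini-batch SGD (batch 32) with Adam at learning rate 0.01 on
binary cross-entropy; weights are initialized i.i.d. N(0, 0.01²), biases
zero. All layers, backpropagation and Adam are implemented in NumPy; a
run is bit-reproducible on CPU given the seed, which drives
initialization, shuffling and dropout together. Class-imbalance
reweighting exists as an option but is off by default. Cross-validation
is stratified k-fold (default k = 5); stratification is a deliberate
addition because screening datasets are heavily imbalanced and
unstratified folds can end up single-class.

## Receptive-field geometry and masking

For each final-layer unit, `traceback_span` returns the input-row
interval that influences it, composed layer by layer from (window,
stride, padding). With `input_len` given, clipping happens *per layer*,
so windows hanging over a padded edge do not inflate the span: the
result is the exact extent of real input rows. Two verified subtleties:

- If every layer has stride ≤ window, the influence set is exactly the
  returned interval (perturbation-oracle equality, tested over random
  architectures). A layer with stride > window leaves gaps; the interval
  is then a tight outer bound.
- The closed-form bound on the span at stride 1 with pool window ≤ k₁ is
  2k₁ + k₂ symbols (21 at defaults; the exact span at defaults is 19).

Positions whose receptive field lies entirely in padding are masked out
of the global max by default (`mask_padding`), so motifs can never be
called inside zero-padding and a compound's SCFP does not depend on how
much padding follows it.

## Motif calling

Per-filter means and variances of the global-max values are estimated
over a reference dataset; fingerprints are Z-scored with them, and
filters with z > 2.58 are reported. 2.58 is the two-sided 99% standard
normal critical value (the 0.995 quantile to two decimals; the one-sided
99% value would be 2.33). Zero-variance (dead/constant) filters
are excluded rather than yielding infinite Z. One hit per qualifying
filter is reported at the activation argmax (ties broken toward the
lowest position, for determinism); Z-scoring is used only for motif
calling, never for training or prediction.

The choice of reference dataset matters and is a deployment assumption,
not a free parameter: the Z > 2.58 rule presumes the reference
distribution is dominated by compounds that do *not* carry the motif, as
in real screening collections (typically 1:10 to 1:20 active:inactive).
A filter that fires on a fraction p of the reference set can reach at
most z ≈ √((1−p)/p) for its firing class — about 1 for a balanced set,
about 3 at 1:10 — so calling against a 50/50 reference censors almost
all true positives. The recovery experiment in the test suite therefore
trains on a balanced set (for gradient and evaluation power) but fits
filter statistics on a 1:10 screening-composition reference.

`embed_chemical_space` provides the comparison utility: metric MDS to two
dimensions of either SCFP or 1024-bit radius-2 circular (Morgan/ECFP)
fingerprints computed via RDKit.

## Synthetic benchmark

`generate_planted_dataset` emulates a small-molecule screening set:
scaffolds of 8–30 heavy atoms assembled as random valence-respecting
trees over {C (weighted ×5), N, O, S, F, Cl} with branch probability 0.3
and ring probability 0.3 (single ring closure, size 4–7), serialized to
canonical SMILES. Actives receive one copy of a planted fragment —
default `C(=O)O`, a carboxy-like group — attached at a random H-bearing
scaffold atom; inactives are rejection-sampled to be verifiably
motif-free by substructure search. Ground-truth motif atoms are
recomputed on the canonical molecule by substructure matching, because
canonicalization permutes atom order. Labels agree with an independent
substructure oracle by construction, and generated token lengths stay
well below the default matrix length.

What this does **not** emulate: realistic drug-like chemistry (no
aromatic ring systems beyond what ring closure produces, no stereo
centers, no charged species in scaffolds), label noise, activity cliffs,
or multiple competing pharmacophores. Passing the planted-motif tests
demonstrates that the pipeline learns and localizes a separable
substructure signal end to end; it does not certify performance on real
assay data. The scaffolds use single bonds only, so the planted
fragment's double bond itself carries class signal — deliberate, to make
recovery attributable.

## Problem sizes and numerical choices

The end-to-end experiments in the test suite use 200 actives + 200
inactives, matrix length 100 (the generated sets' token maximum rounded
up), the default 128/64-filter architecture, and 30 training epochs —
sizes at which the separable task converges (held-out ROC-AUC reaches
1.0 within ~5 epochs) and the whole suite runs in about a minute on one
CPU core. The permutation baseline for motif recovery uses 500 draws of
random spans with the observed widths. Degenerate inputs are handled
explicitly: empty datasets, single-class label sets, sequences shorter
than the layer stack, unmatched rings/brackets, and over-length inputs
(error by default, truncation on request) all raise typed errors.

## Known limitations

- Single-task binary classification only; the 12-assay joint
  (multi-head) setting is out of scope.
- Motifs are single-filter, single-position reports; merging overlapping
  filters into larger composite motifs is not implemented.
- Tokenization targets canonical RDKit output, not the full OpenSMILES
  dialect (no reactions, wildcard atoms, or atom maps).
- CPU-only NumPy training; practical for 10²–10⁴ compounds, not for
  large-scale hyperparameter searches.
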