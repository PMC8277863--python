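# Methods

## Molecular representation

A molecule is a *master graph*: nodes are heavy atoms labeled by element
(alphabet {C, N, O, P}, configurable), edges are covalent bonds labeled by
integer order 1, 2 or 3, and hydrogens are lumped — each node stores its
hydrogen count, and a hydrogen-only species (H2) is a zero-node graph with
a recorded hydrogen total.  Descriptors are strictly two-dimensional;
stereochemistry, conformers and charged species are out of scope.

Design choices where the representation was genuinely open:

- **Aromaticity.** The edge alphabet has no aromatic order, so all
  aromatic perception is kekulized to alternating single/double bonds
  before graph construction (benzene's bond-order multiset is exactly
  {1: 3, 2: 3}).  Aromatic rings are therefore captured only indirectly,
  through fragments such as C-C=C-C=C.  Unkekulizable input is rejected.
- **Radicals** are allowed.  Hydrogen counts follow the input's explicit
  valence (what the SMILES/MOL block says), never a forced standard
  valence, so species like phosphorus dioxide parse with zero hydrogens.
- **Rejections.** Elements outside the alphabet (named in the error),
  disconnected multi-component structures, and species with net formal
  charge are rejected rather than silently coerced.

## Canonicalization

Fragments are identified up to isomorphism by a canonical key: the
lexicographic minimum over node orderings of the label sequence plus the
upper-triangle bond-order matrix (absent edge = 0).  Only orderings that
sort the labels are searched, which is exact and, at fragment sizes of at
most `max_edges + 1 = 5` nodes, cheap (≤ 5! permutations before
pruning).  Keys are plain text (`"C,C,O|102"`), so registries diff and
serialize cleanly.  The whole-molecule variant appends hydrogen counts to
the labels and is intended for small molecules only; identity of larger
molecules is checked through canonical SMILES instead.

## Fragment enumeration and the feature matrix

The counting unit is the **distinct connected edge subset**: every subset
of 1..`max_edges` edges that induces a connected subgraph is counted once,
grouped by canonical key.  Symmetric fragments are *not* multiply counted
per automorphism — embedding-counting would inflate symmetric groups and
break the per-occurrence energy reading of the coefficients.  Subsets are
grown breadth-first from single edges by incident-edge extension with
frozenset deduplication, which is exhaustive and fast at the default
cutoff of 4 edges (cyclobutane, for example, yields the 4-cycle once and
the 3-edge path four times).  Edge-subset (not node-induced) enumeration
is a deliberate convention: a node-induced convention would merge
ring-with-chord cases.

Zeroth-order descriptors are the per-element node counts plus one special
lumped-hydrogen column equal to the molecule's total hydrogen count.
The feature table's columns are ordered by ascending edge count, then
lexicographic key, so tables are deterministic and row order never
affects column content.

## Error model

The response is y = ΔHf(reference) − ΔHf(computed) in kcal/mol (positive
= underprediction).  The fit minimizes

    (1/2n) Σ_i (x_i·w − y_i)² + λ‖w‖₁

by coordinate descent (scikit-learn's solver; tolerance 1e-6, iteration
cap 1e5; λ = 0 falls back to least squares).  The 1/n-averaged form makes
λ comparable across sample sizes.  Defaults that preserve the
group-energy interpretation, both configurable:

- **No intercept.**  The atom-count columns already absorb any offset.
- **No standardization.**  Coefficients stay kcal/mol per occurrence.

λ is selected on a 60-point log grid from λ_max = max_j |X_jᵀy|/n down to
1e-4·λ_max by k-fold CV (default tenfold, seeded shuffle), minimizing
mean out-of-fold squared error with ties broken toward the larger λ
(sparser model).  Coefficients with |w| ≤ 1e-8 count as inactive — the
solver returns exact zeros, but the guard keeps "active" solver-agnostic.

Prediction sums w_j·d_ij over the molecule's fragments; fragments outside
the model registry contribute zero and raise a coverage warning (a
scientifically meaningful event: an uncovered fragment means the training
set never saw that chemistry).  Correction adds the predicted error to the
computed enthalpy.  Reaction error accumulates integer net fragment counts
(products minus reactants) *before* multiplying by coefficients, so
element-balanced reactions cancel atom-level corrections to exactly 0.0 in
floating point — the formal basis of the error-cancellation heuristic, and
a diagnostic for when it fails (reactions breaking/forming high-coefficient
bonds).

## Uncertainty quantification

The 90/10 train/test split is seeded and fixed; the test partition is
never resampled.  Bootstrap assessment repeats, per iteration, a random
60/40 split of the training rows (default 1000 iterations), refits the
full pipeline — λ re-selected by CV inside each iteration by default, to
expose full-pipeline uncertainty; a frozen-λ mode exists — and records
train/validation MAE, P(ε < threshold), λ, and the coefficient vector.
The stated "with replacement" language of classical bootstrap is exposed
as an optional mode (fit rows drawn with replacement, validation on
unsampled rows); the plain split is the default because it keeps the 40%
validation set exact.  From the per-iteration samples, which are pure
inputs to every summary:

- **P(ε < t)** = (1/N) Σ H[t − ε_i] with H[0] = 1: an error exactly at
  the threshold (default 2 kcal/mol) counts as within it.
- **Normalized model frequency** of group j = fraction of iterations with
  |w_j| > 1e-8 — a selection-stability measure that is more robust than
  coefficient error bars when descriptors are collinear.
- **Coefficient CIs**: percentile intervals (linear-interpolation
  quantiles, pinned for reproducibility), default 95%.

Learning curves refit the pipeline on seeded subsamples of the training
rows at each requested fraction and record test-set MAE; the group
correlation diagnostic reports |Pearson r| between active columns
(constant columns are flagged NaN, never silently zeroed) — small
off-diagonals justify reading coefficients as independent group energies.

All loops consume one `numpy` Generator seeded once, so identical seeds
reproduce every artifact bitwise.

## Synthetic data

The generator emulates a thermochemistry benchmark set: heavy-atom count
uniform on 1–12, elements drawn with probabilities C 0.70 / N 0.10 /
O 0.15 / P 0.05, molecules grown as random trees with ring closures
(probability 0.15 per closure attempt), bond orders drawn with
probabilities 0.80/0.18/0.02 subject to standard valences (C 4, N 3, O 2;
P trivalent with probability 0.7, else pentavalent), leftover valence
filled with lumped hydrogens.  Unsatisfiable draws are resampled
internally; every emitted graph is connected, valence-valid, and
round-trips through the parser.

The default truth model mirrors the structure of real functional-error
models — dominant zeroth-order atom energies, a couple of single-bond
terms, small higher-order fragments: C 11.65, H −3.01, O 14.59, N 10.39,
N-O 5.35, C-N 1.15, C-C=C 1.72, C-C=O −0.85 kcal/mol, plus Gaussian noise
(σ = 1 kcal/mol by default).  The two higher-order groups use common
double-bond motifs so the generator's chemistry expresses them at useful
frequency.  Responses are y_i = Σ_g w*_g d_ig + ε_i; exported CSVs set
h_reference = h_computed + y with placeholder Gaussian computed values,
since only the difference carries information.

**What passing tests do and do not show.**  The synthetic errors are, by
construction, exactly group-additive plus i.i.d. noise; real functional
error is only approximately so (residual ~4–5 kcal/mol "random" error
remains after correction on real data).  Recovery and correction results
on synthetic data therefore validate the machinery — enumeration,
selection, calibration, reproducibility — not the physical accuracy
attainable on any particular level of theory or dataset.  Rare-fragment
pathologies seen in practice (a fragment present in one molecule only
cannot be learned) are likewise under-represented at these settings.

## Problem sizes and numerical choices

Unit tests run on 80–300 generated molecules.  The end-to-end study uses
1500 molecules (~2000 candidate fragments), tenfold CV on the default
60-point grid for the single fit, and a 25-iteration bootstrap with a
25-point grid from λ_max to 1e-3·λ_max inside resampling loops — a grid
density choice that leaves selection behavior unchanged on this data
while keeping repeated CV affordable; `scripts/acceptance.py` uses the
same sizes.  The 1000-iteration default remains appropriate for one-off
production analyses.

## Known limitations

- Permutation canonicalization is factorial; it is intended for
  fragments (≤ 5 nodes), not whole molecules.
- The fragment alphabet is bounded by `max_edges`; chemistry whose error
  lives in larger motifs (full aromatic rings, fused systems) is captured
  only through overlapping smaller fragments, and raising the cutoff
  increases descriptor collinearity.
- Only neutral, single-component C/H/O/N/P species are supported.
- LASSO solutions under collinear descriptors are one member of a family
  of near-equivalent sparse models; interpret individual coefficients
  jointly with their normalized model frequency, not in isolation.
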