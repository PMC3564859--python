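# Methods

## The comparison problem

A dynamical system observed over time — a biochemical network simulation, a
stock index, a multichannel physiological recording — yields a multivariate
time series: an unordered bag of named univariate component traces sampled
at common, equally spaced time points. Two such systems rarely share a
dimension, which rules out the classical multivariate distances. SMETS
compares them anyway, in two stages: a greedy partial matching of the most
similar components, and penalties for what the matching could not use.

## Univariate preprocessing and representation

Each component is processed independently:

1. **z-normalization** — subtract the mean, divide by the standard
   deviation, so that only shape differences remain. The *population*
   (divide-by-q) standard deviation is used; the choice is invisible
   downstream but is fixed for reproducibility. A zero-spread (constant)
   trace maps to all-zeros rather than raising: flat components are
   legitimate model behaviour with zero information content, and they must
   survive preprocessing.
2. **Zero-padding** to the next power of two, as the dyadic Haar transform
   requires. When two series of different lengths are compared (or a whole
   collection is analysed), all series are padded to the *common* power of
   two so their coefficient spaces align. Normalization precedes padding;
   padding a series and then normalizing would shift every value by the
   padded mean and destroy the all-zeros encoding of constants.
3. **Haar DWT** in the orthonormal (1/√2-scaled) convention, computed by
   PyWavelets with periodization; the full multiresolution vector
   [approximation, coarsest details, …, finest details] has the same length
   and, by Parseval, the same energy as the input (checked to 1e-9).
   Orthonormality is what makes Euclidean distance in coefficient space
   equal the raw distance before truncation — the starting point for lower
   bounding.
4. **Top-k retention** — keep the k = 16 coefficients of largest magnitude
   together with their positions (ties broken toward the lower index for
   determinism), then **truncate** the retained set to 15 symbols by
   dropping the largest transform indices. Zero-padding contaminates the
   finest-scale coefficients over the padded tail, which sit at the end of
   the multiresolution vector; dropping the trailing retained symbol
   removes that bias. Both k and the truncation target are settings
   (`wavelet.k`, `wavelet.truncate_to`); k is clamped to the padded length
   and truncation is skipped when it would not shrink the set. The wavelet
   stage can be disabled entirely (`wavelet.enabled: false`), in which case
   the normalized, padded series itself is the (lossless) representation.

### Distance between representations, and lower bounding

Distances between representations must never exceed distances between the
underlying series ("no false dismissals"). With per-series top-k retention
the naive rule — treat absent positions as zero — does **not** guarantee
this: when two similar series retain slightly different position sets, a
boundary coefficient kept by one side and dropped by the other is counted
at full magnitude against an implicit zero, and the estimate can exceed the
raw distance (empirically on about a quarter of near-identical random pairs
at k = 16). Each representation therefore stores a *threshold* ε: the
largest magnitude among its discarded coefficients (updated when the
truncation step discards more). The distance is then

- positions retained by both sides: exact difference;
- positions retained by one side only, coefficient c: max(|c| − ε_other, 0),
  the smallest difference consistent with the other side having discarded
  something of magnitude at most ε_other;
- positions retained by neither: zero.

Since |c − c_dropped| ≥ |c| − ε_other and every omitted term is
non-negative, the result provably lower-bounds the raw Euclidean distance;
when nothing was discarded (ε = 0, e.g. k = full length) it reduces exactly
to union-of-positions with implicit zeros, and with k = full length it
equals the raw distance. Representations carry a fingerprint of their
pipeline settings and padded length; distances across incompatible
pipelines are refused.

## The SMETS distance

For series A, B with dimensions n ≤ m (the first argument takes the
"smaller" role on ties; the value is symmetric either way):

1. **Greedy partial matching.** Compute the n×m cross-distance matrix
   between representations. Repeatedly select the globally smallest
   remaining entry (ties broken to the lexicographically smallest
   (row, column) pair), record the distance, and retire both components,
   until all n components of the smaller series are matched. This
   guarantees a one-to-one partial matching; identical components shared
   by both series always match at distance zero. The matched distances d
   are aggregated as ‖d‖ₚ with p = n, computed in scaled form so large
   values and large p do not overflow.
2. **Entropy penalty.** Every unmatched component j of the larger series
   has a nearest-counterpart distance d_j — the minimum of its column in
   the *original* (pre-removal) matrix — and a Shannon entropy
   H_j = −Σ_v f(v) ln f(v) over the empirical frequencies of its values,
   computed on the normalized, pre-padding trace (entropy is invariant
   under the affine normalization when exact frequencies are used).
   EP = Σ_j (H_j / Σ_k H_k) d_j over the unmatched set, a
   information-weighted mean on the scale of a single univariate distance:
   high-information unmatched components dominate, constant ones contribute
   nothing, and EP = 0 when nothing is unmatched or all unmatched entropies
   vanish. Exact value frequencies are the default; for continuous data,
   where every value is distinct and the entropy saturates at ln q, an
   optional uniform quantization (`entropy.bins`) coarsens the alphabet
   first. H is measured in nats, 0 ≤ H ≤ ln q.
3. **Dimension penalty.** P = (m − n)/(m + n) ∈ [0, 1). It restores the
   identity property when all unmatched components are flat, and increases
   strictly with the dimension gap.

SMETS(A, B) = ‖d‖ₙ + √(EP² + P²). The penalty enters through a 2-norm so
that the dimension term does not dominate well-matched comparisons. With
‖d‖ = EP = 0 the distance equals P exactly, which is what the three-model
worked example isolates (0.25, 1/3, 7/13). The combination is
non-negative, symmetric, reflexive, and zero only for identical
preprocessed inputs. The triangle inequality holds when n = m (verified on
randomized triples) but can fail across dimensions: detouring A→B→C
through a low-dimensional B can cost two small penalties where the direct
equal-dimension comparison A→C must pay a full matched distance — the test
suite constructs such a witness. Complexity is O(m³) in the larger
dimension (m rounds of an O(nm) scan plus the matrix itself).

## Collection analysis

`build_distance_matrix` pads the whole collection to one common length,
prepares each series once, and fills the symmetric pairwise matrix.
Agglomerative hierarchical clustering uses scipy with *average* linkage by
default (single/complete available) — the linkage criterion is a free
choice here, and average linkage is the conventional default. Trees export
as Newick (via scikit-bio) and as a tab-separated merge table; matrices as
labelled CSV and optional grayscale heat maps. The classical baseline —
Euclidean distance between (weighted) pointwise average traces — is
provided for side-by-side comparison; no agreement between the two
matrices is expected, the method's point being that averaging destroys
information.

## Synthetic models

The generator produces the component archetypes whose comparison the
method is designed for: sinusoids (period 20 samples, amplitude 1,
optional exponential damping), exponential relaxations with staggered time
constants, constant traces, and stock-like Gaussian random walks.
Component shapes are deterministic functions of the spec parameters; the
seed feeds only observation noise (default 0) and the random walks, so two
specs sharing oscillator settings produce bit-identical oscillators — the
property the worked-example trio relies on. Default length is 100 samples
(padded to 128), which keeps the example at the paper-figure scale while
exercising the padding and truncation paths.

What the synthetic data does *not* emulate: cross-component correlations,
measurement trends, missing samples, heavy-tailed noise, or the scale of
real portfolios (hundreds of components, thousands of time points).
Passing tests therefore demonstrate the correctness of the machinery and
the claimed metric properties, not performance on any real data domain.
Randomized suites use heterogeneous models (mixed sinusoid / relaxation /
walk components with 5% observation noise), where cross-distances are
almost surely tie-free; sizes (dimensions ≤ 10, lengths 16–128, 1000
repetitions) were chosen to exercise all code paths at desk scale.

## Numerical choices and degenerate inputs

- Magnitude ties in top-k retention and distance ties in the greedy
  matching are broken toward lower indices: results are deterministic and
  invariant to component order whenever cross-distances are distinct.
- Constant traces: normalize to zeros, transform to zeros, entropy 0.
- Series shorter than k: k is clamped; truncation skipped if not shrinking.
- Zero-entropy unmatched sets: EP defined as 0 (no 0/0).
- The p-norm is evaluated as max(d)·(Σ(dᵢ/max)ᵖ)^(1/p) to avoid overflow.
- Ingestion rejects missing cells and non-increasing timestamps, and warns
  (but proceeds) on non-uniform spacing — the method assumes equal spacing
  and no interpolation is attempted.

## Known limitations

- The entropy weighting normalizes over the unmatched set only; weighting
  by the larger series' total entropy is a defensible alternative that
  would shrink EP when most components are matched. The chosen form keeps
  EP on the scale of one univariate distance and realizes the intended
  behaviour (constant traces free, informative traces costly).
- No time alignment: components shifted in phase are simply distant; DTW
  or LCSS could be plugged in as the univariate distance but are not
  provided.
- Lower bounding is guaranteed relative to the *padded, normalized* series,
  the space in which all comparisons are made.
- The representation threshold makes compressed distances slightly more
  conservative (smaller) than plain zero-filling when retained sets
  disagree; at k = 16 of 256 coefficients the effect on smooth data is
  small, and it vanishes for lossless representations.
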