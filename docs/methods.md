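# Methods

This note records what the package computes, the assumptions behind each
stage, the parameters that matter, and the choices made where the design
was genuinely open.

## Signal representation

A DNA sequence over {A, C, G, T} is mapped to the cumulated phase of its
complex-number representation (A→1+j, C→−1−j, G→−1+j, T→1−j). Because the
four arguments are ±π/4 and ±3π/4, the cumulative sum at position *k*
reduces to the prefix-count form

Θ_cum[k] = (π/4)·[3(n_G − n_C) + (n_A − n_T)].

Two independent implementations (prefix counts and literal angle
accumulation) are kept and cross-checked in the tests; they are
algebraically identical and must agree to ≤ 1e−9.

Properties the representation guarantees, all under test: one sample per
nucleotide (positional information preserved); per-step increments of
exactly π/4 or 3π/4 in magnitude; additivity under concatenation; final
value invariant under sequence reversal (counts are order-free). The phase
is accumulated unwrapped — it is an unbounded cumulative sum, and its slow
drift is exactly what the detrend stage later removes.

**Ambiguous bases.** `N` contributes angle 0 (phase held flat) and
increments no count: length bookkeeping is preserved without biasing the
trend toward any base. A `strict=True` mode raises instead, for pipelines
that must not silently accept ambiguity. Other IUPAC codes are rejected at
parse time: the mapping defines four symbols, and guessing a phase for,
say, `R` would inject spurious trend.

## Coordinates

All genomic coordinates are 1-based and inclusive on both ends
(`length = end − start + 1`), the GenBank convention. The ten-organism
ACTA1 gene panel (accession, chromosome, start, end) ships with the
package as reference input data; the tests check the derived lengths.

## Preprocessing

Fixed stage order: **median filter → downsample → normalize01 → detrend**.

- **Median filter**, default window 4. Even windows take the mean of the
  two central order statistics; edges truncate the window so output length
  equals input length (required by downstream bookkeeping). Purpose:
  single-sample excursions (individual substitutions) should not drive the
  comparison; the trend should.
- **Downsampling**, default factor 10 for ~3 kb genes. Anti-alias
  zero-phase polyphase FIR low-pass (cutoff at half the new Nyquist) then
  decimation keeping every factor-th sample (output length ⌈n/f⌉). Edge
  samples use edge-value padding, so a constant signal passes through
  exactly. The factor can instead be estimated (`"auto"`): the largest
  k ≤ max_auto_factor whose retained band (normalized frequency < 1/(2k))
  holds ≥ 99.5 % (configurable) of the mean-removed spectral power, by
  direct one-sided periodogram summation; k = 1 if no k ≥ 2 qualifies; a
  constant signal (all power at DC) returns the cap with a logged note.
  Cumulated-phase signals have random-walk-like ~1/f² spectra, so for
  ~3 kb genes the rule lands near the fixed default of 10.
- **Normalization** to [0, 1] by linear min-max rescale; a constant signal
  maps to all zeros (degenerate but harmless: downstream distances are 0).
- **Detrendization**: subtract a least-squares polynomial (default order 4)
  fit on the sample index rescaled to [0, 1] for conditioning. Order 0 is
  mean-centering. Residuals are orthogonal to the fitted basis (under
  test). The cumulated phase's global drift carries composition, not
  position, information; removing it leaves the local segment structure
  that alignment should compare.

Ordering note: normalization precedes detrendization in this pipeline; the
alternative order is representable by calling the stages directly. The
whole chain is deterministic and invariant to an additive offset and
positive scaling of the input (normalize01 absorbs both; under test).

## DTW alignment

Local cost d(i,j) = |x_i − y_j| (squared cost available). The accumulated
table follows the standard symmetric step pattern
D(i,j) = min[D(i−1,j−1), D(i−1,j), D(i,j−1)] + d(i,j); backtracking from
(N,M) to (1,1) prefers diagonal, then vertical, on ties — deterministic
and biased toward the shortest path. The table kernel is numba-compiled;
a two-row rolling variant returns only D(N,M) with an identical-result
contract (under test). An optional Sakoe-Chiba-style band restricts the
path to a diagonal corridor; measured on synthetic families it changes
distances only marginally, so it is off by default and kept as a
speed/regularity control.

**Two normalized distances.**

- `warped_euclidean`: sqrt(Σ_k (x[i_k]−y[j_k])²) / L over the warping path
  of length L — the Euclidean distance of the sample-repeated ("adapted")
  pair, normalized to the aligned length.
- `path_cost`: D(N,M) / L — mean local cost per path step.

`dtw_distance` defaults to `warped_euclidean`. Distance-matrix
construction (`pairwise_matrix`) defaults to `path_cost`, for a measured
reason: dividing a square-root sum by L rewards path lengthening, so under
heavy warping the warped-pair form can *decrease* as signals diverge —
on synthetic families it produced between-clade distances smaller than
within-clade ones. The path-cost form cannot improve by lengthening the
path this way and stays monotone in divergence, which is the property
cluster analysis needs. Both variants are exposed everywhere.

DTW here is a dissimilarity, not a metric: symmetry and identity hold
(under test), the triangle inequality does not in general. Symmetry is
exact for generic (tie-free) inputs; at exact ties the tie-break can pick
different equal-cost paths for (x,y) and (y,x), which changes the
warped-pair distance but never the path cost.

## Clustering and node support

Distances are min-max normalized to [0, 1] over the off-diagonal entries
(raw signal distances have no physical scale for a dendrogram; only
relative similarity matters). Normalization is monotone, so it never
changes UPGMA topology (under test). UPGMA merges the closest pair, ties
broken on the lexicographically smallest pair of cluster representative
labels (deterministic under relabeling/reordering); merged distances are
size-weighted arithmetic means; node height is half the merge distance.
On any ultrametric input the reconstruction is exact (cophenetic
round-trip under test, plus a scipy average-linkage cross-check).

**OTU jackknife.** Pairwise signal distances do not change when a taxon is
removed — unlike multiple alignment, where removal can reshape the whole
alignment — so the pairwise matrix is computed once and subset per
replicate. Each replicate removes r taxa, r uniform on [1, n−3] (the cap
keeps pseudotrees able to contain informative bipartitions), rebuilds the
UPGMA tree, and checks each original node's bipartition restricted to the
survivors. Support = 100 × recoveries / testable replicates, where a node
is testable when ≥ 2 taxa survive on each side. Removal draws use the
sorted label set, so supports depend only on the seed and the taxon set,
not input order. Column bootstrap is deliberately absent: these distances
depend on whole-signal trends, not exchangeable positions, so resampling
columns has no meaning here.

## Synthetic gene families

The generator emulates the structure the method assumes: alternating
conserved exon blocks and length-variable intron blocks evolved down a
known ultrametric tree.

- Exon sites substitute with probability 1 − exp(−rate·t) per branch of
  length t, uniformly over the three alternative bases.
- Intron sites substitute at `intron_rate_multiplier` (default 3×) the
  exon rate — non-coding sequence diverges faster.
- With probability 1 − exp(−indel_rate·t) an intron redraws its length
  from the configured range by deleting or inserting one contiguous
  segment at a random position, retaining most of its content.

The intron model is deliberately *smooth*: an earlier variant that
replaced a resampled intron with fresh random content made distances jump
in large discrete steps whenever a single resample event occurred, which
destroyed the rank agreement between signal distances and true tree
distances. Indel-style length changes keep divergence clock-like while
still shifting the conserved blocks between lineages — the phenomenon the
warping alignment exists to absorb.

Defaults emulate a skeletal-muscle alpha-actin (ACTA1) family: 7 exons of
162 bp (a 377-residue product plus stop ≈ 1134 bp coding) and 6 introns of
200–400 bp, giving ~2.9 ± 0.3 kb totals; substitution rate 0.1 per site
per unit branch length; indel rate 0.5. The `two_clade_10` preset has ten
leaves in two clades — a quartet `((A1,A2),(A3,A4))` and a six-leaf clade
`(((B1,B2),(B3,B4)),(B5,B6))` — with geometrically spaced merge heights
0.004 / 0.03 / 0.25 and a deep root at height 2.0.

**Why geometric spacing and no lone deep leaves.** A distance estimated
from one gene's signal is a single realization of an accumulated-offset
process; its relative sampling noise is large (~30–40 %, measured) and
insensitive to detrend order and downsampling factor. Distances also grow
sublinearly with divergence and saturate once signals decorrelate.
Consequently UPGMA decisions are only reliable when successive true merge
levels differ by large ratios, and when no decision hangs on a single leaf
pair (a lone fifth leaf per clade made root placement flip in ~⅓ of
simulations). Under the defaults, the preset family is recovered exactly —
correct unrooted topology *and* both clade nodes present — in roughly
80–90 % of random seeds; the fixed-seed test fixture (seed 0, the package
default) recovers with all node supports at 100 %.

What the simulator does **not** model: per-base indels in exons, codon
structure, rate heterogeneity across sites, base-composition bias,
recombination, and real intron boundary motifs. Passing the synthetic
tests therefore demonstrates the pipeline's mechanics and its segment-
shift robustness, not calibrated accuracy on real genomes.

## Numerical choices and degenerate inputs

- Even-window medians: mean of the two central order statistics; edge
  policy: truncation (length-preserving).
- normalize01 of a constant signal → zeros, not an error.
- All-equal off-diagonal distances normalize to zeros with a warning.
- Polynomial fits use the index rescaled to [0, 1].
- Newick branch lengths are rounded to 10 decimals on output.
- All randomness (simulation, jackknife) flows from explicit integer
  seeds through `numpy.random.default_rng`; identical seeds reproduce
  byte-identical outputs.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data at
the study scale the package targets: ten ~3 kb sequences (≈ 300-sample
preprocessed signals, 45 DTW alignments), 1000 jackknife replicates, plus
a no-downsampling comparison at full ~3000-sample resolution for the
downsampling-sensitivity figure. Exhaustive-enumeration DTW oracles use
signals of length ≤ 6, where every monotone path can be walked.

## Known limitations

- Single-gene distances are noisy estimators; closely spaced tree levels
  (height ratios ≲ 2) are not reliably resolved. Averaging over multiple
  genes would reduce this but is out of scope.
- The warped-pair Euclidean distance is faithful for mild warping only;
  for clustering use the path-cost default.
- UPGMA assumes clock-like divergence; strongly rate-heterogeneous
  families will be misrooted regardless of distance quality.
- Preprocessing parameters (median window, factor, polynomial order) are
  per-dataset choices; defaults suit ~3 kb genes and should be revisited
  for very different lengths or gene structures.
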