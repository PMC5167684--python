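# Methods

## The task and the model

Fluorescent proteins are labelled with one of two oligomeric states,
monomer or oligomer, and the state is predicted from the amino acid
sequence alone. The classifier is a single C4.5-style decision tree over
numeric sequence descriptors. A tree is deliberately chosen over stronger
learners: its split rules name the exact descriptors (residues, dipeptides,
tripeptides, property profiles) that separate the classes, which is the
scientific payload — oligomerization interfaces are enriched in hydrophobic
residues, and an interpretable model can surface that directly.

The package is organised around a Model/Results pair:
`OligomerStateModel` binds a feature table and labels (constructed from
FASTA + CSV via `from_files`, or from records via `from_sequences`);
`fit()` returns a results object with the induced tree, the pruning record
and training diagnostics; `benchmark()` runs the resampled evaluation
protocol. The underlying stages are importable modules
(`sequence_io`, `descriptors`, `homology`, `feature_selection`, `tree`,
`evaluation`, `synthetic`) and a thin `oligostate` CLI drives them.

## Descriptors

All six classes operate on the 20-letter alphabet in the fixed order
`ACDEFGHIKLMNPQRSTVWY`; every vectorized computation is checked in the test
suite against an independent naive-loop implementation at 1e-9.

* **Composition (AAC/DPC/TPC, 8420).** Overlapping k-mer counts divided by
  the number of windows (N, N−1, N−2). Each block sums to 1.
* **Autocorrelation (720).** Eight AAindex scales (CIDH920105, BHAR880101,
  CHAM820101, CHAM820102, CHOC760101, BIGC670101, CHAM810101, DAYM780201 —
  verified against the aaindex data in the seqinr R package), standardized
  to zero mean and unit population SD over the 20 residues, then
  Moreau–Broto (lag-product sum divided by N−d), Moran and Geary forms at
  lags 1..30. The "normalized" Moreau–Broto variant is interpreted as
  standardized-property values with the (N−d) divisor. When the property
  profile has zero variance along a sequence (homopolymers), Moran and
  Geary ratios are defined as 0 with a logged warning rather than NaN, so
  degenerate sequences remain scorable.
* **CTD (147).** Seven Dubchak-style three-group encodings (shipped as an
  auditable TSV). Distribution uses the convention "position of the
  ⌈q·n_r⌉-th occurrence, as percent of N" for q ∈ {first, 25, 50, 75,
  100%}; a group absent from a sequence contributes five zeros.
* **Conjoint triad (343).** Shen-style dipole/volume classes {AGV},
  {ILFP}, {YMTS}, {HNQW}, {RK}, {DE}, {C}; triad counts are max-normalized
  within each sequence.
* **QSO (160).** Coupling numbers τ_d = Σ D(R_i,R_{i+d})² for d = 1..30
  under two residue distance matrices, then per matrix 20 composition-
  derived and 30 coupling-derived quasi-sequence-order values with weight
  w = 0.5. The Grantham chemical distance matrix is reconstructed at load
  time from Grantham's published composition/polarity/volume table and
  formula (α = 1.833, β = 0.1018, γ = 0.000399, scaled to mean 100 over the
  190 pairs; the reconstruction reproduces published values such as
  I–L = 5 and C–W = 215 to rounding). The second matrix is a **synthetic**
  physicochemical distance — Euclidean distance in the plane of the
  standardized hydrophobicity and hydrophilicity scales — standing in for
  the classical Schneider–Wrede matrix, whose published values are not
  packaged; it preserves the construction (symmetric, zero-diagonal
  physicochemical dissimilarity) but not the exact numbers. Both matrices
  are normalized to [0, 1] so coupling terms stay on a scale comparable to
  composition. The composition term uses frequencies N_r/N (the
  denominator is then 1 + w·Στ); counts would give identical ratios up to
  the shared denominator convention.
* **PseAAC (130).** Type 1 uses the three-term squared-difference
  correlation θ(i,j) over standardized hydrophobicity, hydrophilicity
  (Hopp–Woods) and side-chain mass, τ_k averaged over pairs at lag k,
  k = 1..λ; type 2 (amphiphilic) uses hydrophobicity/hydrophilicity
  products giving τ_1..τ_2λ. Both normalize by Σf + w·Στ so the full
  vector sums to 1 (τ may be negative for type 2; the identity still
  holds). λ = 30 and w = 0.5 throughout — λ is forced by the printed
  widths 20+30 and 20+60.

`lag = λ = 30` means every scored sequence must exceed 30 residues; the
synthetic generator therefore enforces a 35-residue minimum.

Production mode (`selected_features` / `--top20`) computes only named
features: composition features are counted one k-mer at a time without
materializing the 8420-wide block; features of the narrow classes are
computed via their class and projected. Values are identical to the
corresponding full-table columns (tested).

## Homology reduction

Greedy longest-first clustering: a sequence joins the first cluster whose
representative it matches at ≥ threshold identity, where identity is
aligned identical positions over the shorter length (so a contained
subsequence scores 1.0). Alignment is a full global alignment (match +1,
mismatch 0, gap open −1, extend −0.5 via Biopython's PairwiseAligner)
rather than CD-HIT's k-mer screen: at hundreds of sequences the exact
computation is affordable and auditable. An exact composition bound —
shared residue counts over the shorter length — skips alignments that
provably cannot reach the threshold; it can never exclude a pair that
could, so results equal the unfiltered algorithm. Ties in length keep
input order, making runs reproducible. At threshold 1.00 the procedure
reduces to exact-duplicate removal on data without containment pairs
(checked against hash-based deduplication).

## Collinearity pruning

The classic iterative findCorrelation rule at cutoff 0.7: take the worst
offending pair, drop the member with the larger mean |r| against the
remaining features, repeat until no kept pair exceeds the cutoff. Because
correlations do not change during removal, the implementation walks a
once-sorted list of offending pairs instead of re-scanning the matrix;
this is exactly equivalent (ties follow row-major order; equal means drop
the later column) and is what makes pruning 8000-wide tables cheap.
Zero-variance columns get correlation 0 by definition and are flagged
uninformative. By default pruning is fitted on the internal split of each
benchmark iteration (leakage-safe); `prune_on="all"` reproduces the
simpler whole-data variant.

## Decision tree

Binary numeric splits only (all descriptors are numeric). Candidate
thresholds are midpoints between consecutive distinct values with at least
`min_leaf` rows on each side; the split maximizing gain ratio wins (plain
information gain behind `criterion="gain"`), ties resolved to the earlier
column and lower threshold; values equal to a threshold route left. Growth
stops on purity, fewer than 2·min_leaf rows, or no positive-gain split.
Pruning is pessimistic subtree replacement: a node becomes a leaf when
n·U(E, n) for the node does not exceed the sum over its leaves, with
U the Clopper–Pearson upper confidence bound on the error rate at
confidence 0.25. Defaults (min_leaf = 2, confidence 0.25) mirror the J48
defaults; subtree raising is not implemented.

A known property asserted in the tests: a perfectly balanced XOR layout
has zero information gain for every root split, so the greedy tree
(correctly) returns a single leaf. Interactions are only found when at
least one participating feature carries marginal signal.

Feature usage is the percent of benchmark iterations whose tree contains
the feature. The SD attached to usage comes from splitting the iterations
into up to 10 contiguous blocks and taking the SD of per-block
percentages — presence in a single run is binary, so spread only exists
across groups of runs.

## Evaluation protocol

Per iteration: a stratified random 80/20 internal/external split
(largest-remainder rounding per class), pruning and tree induction on the
internal set, training-surface metrics from refitting on the full internal
set, tenfold stratified CV on the internal set with confusion counts
pooled over folds, and prediction of the untouched external set. Metrics
are Ac/Sn/Sp (percent) and MCC, positive class monomer; a degenerate MCC
denominator is defined as 0 (random-prediction convention). Aggregation is
mean ± SD (ddof = 1) over iterations; SD is 0 for a single iteration.
Per-iteration seeds derive from the master seed as
`SeedSequence([master, iteration])`, so any iteration is reproducible in
isolation and whole runs are byte-identical under a fixed master seed.
Stratification is a deliberate choice where plain random splitting could
produce single-class folds on small data; pooled-over-folds CV counts are
used rather than per-fold averaging.

## Synthetic study conditions

The generator emulates a curated FP set: by default 100 sequences per
class, lengths uniform in 220–240 residues (FP-like), uniform background
composition (a Swiss-Prot average composition is available as an option),
moderate class signal (strength 0.5). Two signal mechanisms:
`composition_bias` multiplies the frequencies of the hydrophobic residues
{C,L,V,I,M,F,W} by (1 + 2·strength) in the oligomer class, mimicking
hydrophobic oligomerization interfaces; `motif_insertion` plants
⌈3·strength⌉ non-overlapping copies of RMY and LI into each oligomer and
scrubs chance occurrences from monomers, giving constructively separable
data. At strength 0 the classes are identically distributed (the null
control). `make_duplicates` appends copies at exactly (N − mutations)/N
ungapped identity for homology-reduction tests with exact expected counts.

What the generator does **not** emulate: phylogenetic relatedness between
FPs (real sets are mutant series of a few wild types — precisely why
homology reduction exists), chromophore-forming motifs, position-specific
conservation, or realistic class imbalance. Passing benchmarks on
synthetic data therefore demonstrate the pipeline's correctness and
calibration (a separable signal is found; a null signal scores at
chance), not field performance on curated FP data, which depends on the
data set supplied by the user.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the package's
own verification conditions: 25 random sequences of length 35–60 for
descriptor oracles, 1000 records for deduplication equivalence, a
500 × 200 table for the pruning audit, and 25-iteration benchmarks at
100 sequences per class (the full protocol's 100 iterations is the
default of `benchmark()`). Tolerances: descriptor agreement 1e-9
absolute; scale standardization exact to population-SD convention;
split-gain tie tolerance 1e-12; pruning comparison tolerance 1e-9 on
estimated error counts.

## Known limitations

* The greedy tree cannot discover pure interaction effects (XOR-type)
  with zero marginal gain, and like all single trees it is
  high-variance — the benchmark's iteration SDs make that visible.
* Identity at sub-1.0 thresholds depends mildly on the alignment gap
  penalties; published retained-set sizes from other tools (e.g. CD-HIT's
  word-filtered heuristic) may differ by a few sequences at 0.95/0.99.
* The synthetic physicochemical QSO matrix is a stand-in (see above);
  QSO values under it are internally consistent but not comparable with
  tools shipping the Schneider–Wrede numbers. Grantham-matrix QSO values
  are comparable.
* Sequences with non-canonical residues (B, J, O, U, X, Z) are rejected
  by default (or dropped with a warning under the `drop` policy); there
  is no imputation.
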