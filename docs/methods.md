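# Methods

This note documents the model, the algorithms, the tunable parameters and
the deliberate design choices behind `multioverlap`, plus what its
synthetic benchmarks do and do not demonstrate.

## Region model

Regions are BED-standard 0-based half-open intervals; a region `[500, 520)`
covers 20 bp. Strand and BED columns beyond the third are ignored: the
overlap model treats sets purely as position intervals. Input sets are
merged at load time (overlapping *and* abutting intervals fused) so that
per-set occupancy at any base pair is boolean — the null model and the
overlap flags both require this, and window counting merges contiguous
stretches anyway. `read_regions(..., merge=False)` is available for
callers who need raw intervals. Regions exceeding their chromosome are an
error, never clipped silently: clipping hides mismatched genome builds.

## Sweep-line intersection

All region starts/ends ("critical points") per chromosome are sorted once
(O(N log N)); between consecutive distinct coordinates the per-set open
flags are constant, and each maximal constant-flag window with ≥ 2 open
sets becomes one row of the intersection matrix X. Events at an identical
coordinate are aggregated before the next window is emitted, which makes
close-before-open ordering implicit: abutting half-open intervals from
different sets ([500,520) and [520,530)) do not overlap. Because merged
sets never contribute a start and an end at the same coordinate, the net
flag change at every critical point is non-zero, so rows are maximal by
construction. Flags are packed as bits of a uint64, limiting k to 64 sets
(practical analyses use ≤ 20).

## Counting modes

*Exact*: a row counts only toward its own flag pattern; since rows are
maximal, N_exact is the row count per pattern. *Transitive* (default): a
row counts toward every combination whose flags are a subset of the row's;
for N, selected rows that are genomically contiguous are merged first.
This yields the identity

S_transitive(γ) = Σ over {γ′ : γ′ child of γ, or γ′ = γ} S_exact(γ′),

verified exhaustively against a per-base-pair brute-force scan in the test
suite. Transitive counting reads "A + B" as "A + B plus possibly others",
which matches how co-binding is usually interpreted; exact counting is the
right tool when only a full complex (say A+B+C) is believed functional.

## Null model and shuffling

H₀: the positions of regions in different sets are mutually independent.
Each shuffle permutes, per chromosome and per set, the multiset of region
lengths and — independently, as a second series — the multiset of
inter-region gap lengths (m regions have m+1 gaps, counting both flanks to
the chromosome ends, possibly zero-length), then lays them out
alternately. Both multisets are conserved exactly, so regions are *not*
uniformly re-placed: a clumped set stays clumped under the null, which is
what distinguishes this null from naive interval shuffling. Two regions
separated by a zero-length gap after the draw are fused before counting,
consistent with merged-set semantics (total covered bp is conserved; the
region count may drop).

Seeding spawns one `numpy` substream per (shuffle index, set index) from
the master seed, so results are independent of batch size and processing
order, and bit-reproducible. Locked sets keep their true coordinates in
every shuffle; locking all sets is rejected. When a sub-genome restriction
is active, sets are first intersected with the inclusion regions and
remapped onto concatenated pseudo-chromosomes (one per source chromosome,
so concatenation can never manufacture cross-chromosome overlaps), and
shuffling happens in the restricted coordinates.

Per-shuffle intersection rows are retained in compact columnar form and
all tracked combinations are counted afterwards: a combination first seen
in a late shuffle still gets correct (possibly non-zero transitive) counts
for earlier shuffles.

## Statistics

For each combination, the shuffled S values (and N values, treated
identically) are fitted with a Negative Binomial by the method of moments:
p = m/v, r = m²/(v−m) from the sample mean and variance. Moments are
used instead of maximum likelihood for robustness — a small likelihood
perturbation can move the fitted tail by orders of magnitude. The p-value
is the inclusive upper tail P(X ≥ S_obs). Conventions and edge cases:

* **Underdispersed samples (v ≤ m)**: the NB is undefined; a Poisson(m)
  tail is reported with a prominent degenerate flag rather than failing.
  All-zero samples are flagged untestable.
* **Fold change**: m(γ) = log₂(S_obs/S_exp); when either term is zero a
  1 bp pseudo-count is added to both so the value stays finite
  (configurable).
* **Empirical p-value**: (1 + #{samples ≥ S_obs})/(n + 1); the add-one
  rule keeps it positive, floor 1/(n+1).
* **Beta companion**: S/scale (scale = total bp of the analysed
  (sub-)genome) is moment-fitted with a Beta — an approximation of the
  underlying Beta-Binomial. It is flagged low-confidence below 1000
  shuffles; with the default 200 the NB p-value is the one to use.
* **Goodness of fit**: Cramér's V between the shuffle histogram and the
  fitted NB, binned at NB quantiles targeting ≥ 5 expected counts per bin
  (≤ 10 bins); V = sqrt(χ²/(n·(b−1))). Verdict `good` iff V < 0.25; both
  the threshold and the binning are explicit knobs, and fewer than 3
  usable bins yields `untestable`. Poor fits arise mainly when a
  combination is rare in the shuffles; its p-values are then conservative
  while the fold change remains accurate.
* No multiple-testing correction is applied by default; combinations of
  different orders have structurally different nulls and their p-values
  should not be compared directly.

The default of 200 shuffles is enough for a stable moment fit in the
pairwise and low-order regimes; `merge_runs` concatenates independent runs
("superbatches") for large analyses, zero-padding combinations absent from
a run, with fit diagnostics left to be recomputed (conventionally reported
as not assessed).

## MODL itemset miner

Input: the binary overlap matrix (or any binary matrix). Two steps.

**Smothering.** Each unique row pattern with count c is retained
ceil(√c) times. This quadratic damping keeps every pattern (count 1 → 1)
while stripping dominance (count 100 → 10), so minor complexes influence
the reconstruction objective; the trade-off is a mild amplification of
noise patterns, which the later binarization absorbs.

**Library creation.** Sparse dictionary learning (scikit-learn, coordinate
descent, positive code and dictionary)

min ½‖X−UV‖² + α‖U‖₁, rows of V unit-L2,

is run on the smothered matrix over the increasing schedule α₁ = 1/k,
α_{i+1} = α_i + (i+1)/k; higher α forces fewer, longer atoms. After each
factorization, every atom with positive total usage (Σᵢ Uᵢⱼ) is binarized
— items with weight ≥ 0.5 × the atom's peak weight form its membership —
and added to a library deduplicated by membership. The sweep stops when
all usages are zero (or after 20 α values, a safety cap never reached on
realistic inputs). Atoms per factorization default to min(k, q+2): capacity
for the q complexes sought plus slack for noise directions. A failed
factorization is retried with a fresh substream, then skipped with a
warning.

The 0.5 binarization cut is deliberate: under bit-flip noise an atom for a
true complex (E, F) carries low-level weight bled from unrelated items
(e.g. weights 0.24/0.66/0.68 for A/E/F); "at least half the peak weight"
strips these reliably, whereas lower cuts admit the noise item and the true
membership never enters the library.

**Greedy selection.** Starting from an empty dictionary, each step
sparse-codes X (the *raw* matrix — selection quality is judged on the real
data, not the damped one) against the current selection plus each
remaining candidate (as unit-normalized binary vectors) and appends the
candidate minimizing d1 = ‖X−X̃‖₁ + αΣU. Ties break toward smaller
memberships, then lexicographically. The step-2 α defaults to 1/k, the
value that opens the library schedule: a weaker penalty under-prices
coefficients and lets a broad true complex (ABCD) be displaced by a pair of
its fragments (AB + CD), since rebuilding an ABCD row from two
unit-normalized fragments costs 2·√2 in coefficients against 2 for the
single atom — a difference only an adequate α converts into a selection
margin. The unit-L2 normalization itself is what damps overly broad atoms:
an atom spread over j items has entries 1/√j and needs √j-scaled
coefficients, which the ΣU term penalizes. `greedy_select` accepts a
custom error function in place of d1, the hook for supervised variants
(e.g. selecting combinations that help a classifier predict the query);
no such variant ships.

The greedy objective f(S) = −d1 is non-decreasing over iterations by
construction of the argmin (monitored at run time). On the standard
benchmark — complexes AB, ABCD, EF over k = 6 in abundances 0.4/0.3/0.3,
m = 1000 — the q = 3 selection returns exactly the three planted complexes
for 10/10 generator seeds at every flip-noise rate from 0 to 12%, with the
first failures appearing around 16%. Runtime grows roughly linearly in k
(one factorization per α value) and quadratically in q.

## Synthetic data

`gen_region_sets` emulates peak-like data: a query of n fixed-length
regions placed uniformly without overlap (chromosomes weighted by length,
starts by the gap-allocation construction), references that copy a
designated fraction of query regions (each shifted by an independent
uniform jitter in ±j bp) and fill the rest independently, and fully
independent negative controls. `gen_overlap_matrix` draws rows from
planted complex indicators with chosen abundances, then flips each cell
with the noise probability. Defaults are the validation conditions used
throughout: 1000 regions of 100 bp on a 10 Mb chromosome for region sets;
the AB/ABCD/EF matrix above for mining.

What these fixtures do *not* emulate: variable region lengths within a
set, chromatin-driven placement biases, correlated (non-uniform) noise,
signal strengths, or genome-scale chromosome structure. Tests passing on
them validate the algorithms and the calibration of the statistics under
the model's own assumptions — not performance on any particular biological
dataset.

The per-base-pair brute-force oracle shares no code with the sweep: it
paints per-set occupancy bitmasks over an explicit array (guarded to
genomes ≤ 1 Mb) and run-length-encodes them. Sweep and oracle agree
exactly on hundreds of randomized instances per test run.

## Validation scales

The test suite exercises: the toy worked example (S = 20/N = 1 for A+B;
exact 10 vs transitive 20 after adding C); sweep-vs-oracle equality and
the transitivity identity on 100 random instances each (≤ 8 sets, ≤ 50 kb
genomes); null calibration over 50 independent universes of 4 sets ×
1000 regions on 10 Mb with 200 shuffles (fraction of good-fit
combinations at p < 0.05 stays ≤ 0.12 — the NB tail errs conservative);
power (a reference sharing 50% of the query's bp is detected at
p < 0.001 with positive fold change); and moment-fit recovery (r within
10% on 10⁴ NB(5, 0.3) draws). These sizes keep the full suite at a few
minutes on one core while matching the regimes where the model's
assumptions (many regions, small relative to gaps) hold.

## Known limitations

* The NB model is asymptotic; very small sets, very sparse coverage or
  over-restricted sub-genomes produce poor fits (flagged) and conservative
  p-values. Extreme tail p-values (1e-200) indicate ordering, not
  200-digit precision.
* Intra-set overlap structure is deliberately collapsed by merging.
* MODL is approximate by design: it favours abundant complexes over
  high-support association rules, and its smothering step trades some
  noise sensitivity for sensitivity to rare complexes.
* Within-set region identity is not tracked through shuffles.
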