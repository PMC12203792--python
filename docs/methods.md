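# Methods

`oriskew` implements the computational workflow used to compare replication-origin
maps between a wild-type cell line and ORC-subunit-knockout lines, and to estimate
MCM2–7 chromatin-loading rates from flow cytometry. This note records the models,
conventions, numerical choices, and the assumptions behind the synthetic data that
the test suite relies on.

## Coordinates and interval conventions

All genomic intervals are BED-style: 0-based, half-open `[start, end)`. Two
intervals *overlap* when they share at least one base (`a.start < b.end and
b.start < a.end`); touching intervals do not overlap. "Closer than d" is strict
(`gap < d`). Strand is ignored throughout — SNS-seq origin peaks are unstranded.

**Origin definition.** Origins are peaks supported by both biological replicates.
Because "the intersection of the two peak sets" is ambiguous, both readings are
implemented: `mode="region"` (default) emits the base-pair intersection segments,
like `bedtools intersect`; `mode="peak"` keeps whole replicate-1 peaks with ≥1 bp
support in replicate 2.

**Minimum-count Venn overlap.** For two origin sets, peaks are grouped into
connected components of the pairwise overlap graph (on a line this equals
single-linkage chaining). Each mixed component contributes
`min(#a peaks, #b peaks)` to the overlap count, so a component is never counted
more often than its smaller side — the `connectedPeaks="min"` convention of
peak-set Venn diagrams.

**Initiation zones.** The genome-wide median inter-peak distance (adjacent
same-chromosome gaps, `next.start − prev.end`; a start-to-start option exists) is
used as the merge threshold: peaks with gaps strictly below it are chained into a
zone reported as the spanning interval with the member count in the score field.

**CommonKO merge.** Differential origins shared by all three knockout lines are
found by intersecting the three coverages (by Helly's theorem in 1-D, pairwise
overlap of three intervals implies a common base, so seeds are exactly the
triple-intersection regions), expanding each seed to the union span of the peaks
containing it, and merging overlapping spans. All four interval operations are
validated against per-base boolean-array / pairwise-enumeration brute force on
thousands of random small genomes.

## Differential origin classification

Replicates are merged by summing counts and library sizes before normalizing to
RPM (`count / library_size × 1e6`). Library size means total mapped reads in the
sample; a reads-in-peaks alternative is available by passing those totals instead.
An origin is **up** in a knockout when `RPM_KO ≥ 1.5 × RPM_WT`, **down** when
`RPM_KO ≤ RPM_WT / 1.5`; the boundary is inclusive (the 1.5-fold rule does not
state strictness, so inclusion was chosen and is pinned by tests). Classification
happens on the union origin domain with zero-filling: a KO-absent origin with WT
signal is "down", a WT-absent origin with KO signal is "up", and double zeros are
"unchanged" — the only choice closed under classification. These rules make the
classes invariant to global count rescaling and monotone in the threshold.

## Sequence properties and group statistics

GC skew is `(G − C)/(G + C)` and TA skew `(T − A)/(T + A)`, computed on the
reference (+) strand over the whole origin interval (a fixed-flank window option
exists). N bases are excluded; a zero denominator yields skew 0 (logged) rather
than NaN so distributions stay well defined. Reverse complementing negates both
skews and leaves their absolute values unchanged — a property test.

Two-group comparisons follow a normality gate: Shapiro–Wilk per group at
α = 0.05 (configurable; applied per group, the natural reading). If both groups
pass and neither exceeds 5000 points, Welch's t-test with Hedges' g
(pooled-SD standardized difference times `J = 1 − 3/(4(n_x+n_y) − 9)`); otherwise
the Wilcoxon rank-sum test with Cliff's delta
(`(#{x>y} − #{x<y})/(nm)`, computed in O(n log n) by sorted searches and proven
equal to the O(n²) count on random inputs). All tests are two-sided; families of
comparisons are Benjamini–Hochberg adjusted (via statsmodels, pinned against
hand-computed step-up values). Identical constant groups short-circuit to
p = 1, effect 0.

## Permutation colocalization testing

The null model re-places each query interval uniformly at random over all valid
start positions across canonical chromosomes, preserving the length multiset and
never touching masked regions; randomized intervals may overlap one another (the
default of the regioneR-style randomization this emulates; a non-overlapping mode
is a flag away). Overlap is counted as the number of query intervals hit by ≥1
target base, each counted once. With `n_perm` randomizations (default 1000):

- fold enrichment = observed / mean(randomized),
- z = (observed − mean) / sd(randomized), reported as NaN when sd = 0,
- empirical p with the +1 correction, `p = (1 + #{random ≥ observed})/(n_perm+1)`,
  so p is never 0 and lies in `[1/(n_perm+1), 1]`.

Two query sets tested against the same target are compared through their
per-permutation enrichment vectors `e_i = observed/random_i` (zero-overlap
permutations dropped with a warning) using Welch's t-test, BH-adjusted across the
comparison family.

Calibration note: the overlap count is integer-valued, so when its null
distribution is narrow the empirical p is conservative through ties. The
calibration experiments therefore use query/target densities giving the count
enough resolution (hundreds of queries against a ~25%-coverage target on a 10 Mb
genome); at that design the null z is standard-normal to within sampling error
and the 5% rejection rate falls inside its binomial confidence band.

## Replication timing

Repeated per-probe measurements collapse to probe medians; probes map to genomic
positions, and loci whose length changed by more than 5% between assemblies (the
post-liftover sanity filter; the liftover itself is out of scope) are discarded.
Each origin receives the mean of its overlapping probes (nearest-probe mode
optional); origins with no probe are dropped with a logged count. Timing values
follow a higher-is-earlier convention (configurable flag; the statistics are
convention-free). Distributions are compared with the two-sample KS statistic and
the 1-Wasserstein distance (area between ECDFs, via scipy), which for a pure
location shift of equal-sized samples equals the shift exactly — a test identity.

## Ergodic rate analysis

A snapshot of an asynchronous, exponentially growing population encodes the full
MCM-loading time course: in steady state the fraction of cells seen in a stage is
inversely proportional to the speed of passage through it, with younger cells
over-represented by the age density `g(a) = (2 ln 2 / T) · 2^(−a/T)` on `[0, T]`.
After gating G1 MCM-positive events on (DAPI, MCM) and splitting their MCM
intensities into 10 equal-width bins spanning the data min–max (rightmost bin
closed, matching MATLAB `histogram` with `BinLimits`), the per-bin rate is

    W_n = α (2 − F) / f_n,   α = ln 2 / T_doubling,

with `F` the gated fraction of all cells and `f_n` the bin occupancy. The mean
rate averages the per-bin rates. Empty bins are excluded from the mean with a
warning (a literal division would make the mean non-finite; a strict mode keeps
the infinities for comparison). `W_n` has units of 1/hour and is invariant to
rescaling the MCM axis — rates are comparable between samples but carry no
absolute intensity-per-hour unit.

**Gating.** Gates are explicit configuration, not auto-fit: a DAPI window
bracketing the 2N peak, an MCM floor set from a secondary-antibody-only control,
and optionally an MCM ceiling closing the rectangle the way a hand-drawn flow
gate does. The ceiling matters numerically: with data-driven bin limits, a single
extreme outlier stretches the binning and starves the top bin.

## The synthetic study

One configuration object (`SyntheticConfig`) drives every generator; all
generators are pure functions of (config, seed), with fixed per-stage seed
streams so each stage is independently reproducible. Defaults are desk-scale
study conditions chosen once: 2 × 1 Mb chromosomes with 5% randomly masked,
200 core origins of mean length 1 kb (SD 300 bp), 10% line-specific
gains/losses per knockout, 20 planted 2-fold-up and 20 planted 0.5-fold-down
origins, 100 reads/origin with Poisson counts and lognormal (SD 0.1) replicate
library factors, 50 bp replicate boundary jitter, background GC 0.41 (human-like),
planted GC skew ±0.3 with an (ATCC)×8 repeat at planted-up origins,
annotation odds 5 over 300 × 500 bp intervals, a 10 kb probe grid with a +1
early-timing shift at origins, and an HCT116-like cell cycle (T = 19.5 h,
G1 = 0.4 T, S = 0.4 T).

Annotation placement uses the odds parameterization
`p_target = (w−1)ρ / ((w−1)ρ + 1)` (ρ = origin fraction of the unmasked genome),
so `w = 1` reduces *exactly* to the uniform null — required for honest
calibration — and `w → ∞` puts every interval on an origin.

**Flow model.** Cell ages are drawn from `g(a)` by inverse CDF
(`a = −T log2(1 − u/2)`). G1 cells carry DAPI ≈ 2N and load MCM linearly at
`mcm_load_rate` until licensing completes at 80% of G1, then hold a plateau — the
licensing-complete plateau reflects that MCM loading finishes before S entry, and
it also populates the top intensity bin robustly. Through S, DAPI ramps to 4N and
chromatin MCM declines linearly to background; G2 cells sit at 4N. Multiplicative
Gaussian noise (CV 5% MCM, 3% DAPI) is applied and intensities clip at zero.

**Ground truth for the rate estimator.** Because `W_n` is scale-invariant, the
recovery target is the analytic value of the estimand itself:
`expected_ergodic()` integrates the generative model (age density × noise
kernels) over a fine age grid by quadrature, evaluates `F` and the bin masses on
the gate's MCM span, and applies the same `W_n` functional. The Monte Carlo
estimate at 50,000 events matches this closed-form value to within ~1% across
loading rates spanning a 20-fold range, well inside the 15% recovery band the
tests enforce. What this does *not* exercise: instrument-specific spectral
spillover, debris/doublet events, and non-rectangular gate geometry.

**What the generator does not emulate.** Raw reads and peak calling (peaks are
the unit of input), fragment-level coverage, sequence context of real origins
(G4s, CpG islands arise only as abstract annotation tracks), chromosome-scale
replication-timing autocorrelation (probe values are independent given the origin
shift), and cell-cycle arrest or checkpoint dynamics in the flow model. Passing
tests therefore demonstrate the correctness and calibration of the *analysis*,
not biological realism of any particular dataset.

## Problem sizes

The shipped test-suite and acceptance-script runs use: 10 Mb genomes with 200
calibration replicates at 200 permutations; 100 (tests) / 50 (script) seeds for
the power studies at 100 permutations; 20 (tests) / 10 (script) flow samples of
50,000 events; 1000 random instances for the interval brute-force sweep; 500 for
the Cliff's-delta equivalence sweep. These sizes give the statistical resolution
the acceptance bands require.
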