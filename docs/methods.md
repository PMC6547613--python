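# Methods

## The question the package answers

Given directional lists of differentially expressed genes (DEGs) from two or
more perturbation experiments — say, overexpression of a transcriptional
regulator in one experiment and knockdown of a suspected partner in another —
do the lists share more genes than independent draws from the same gene
background would? `degoverlap` answers this with three complementary
statistics and wraps them in a reproducible pipeline that can run either on
real differential-expression tables or on synthetic data with planted,
fully known overlap structure.

## Models and procedures

### Directional DEG calling

A two-condition expression matrix (log2 intensities, ≥2 replicates per
condition) is reduced per probe to a log2 fold change (treatment mean minus
control mean) and a two-sided Welch two-sample t p-value. A probe passes
when the **linear** fold-change magnitude `2^|log2FC|` is strictly greater
than `fc_cut` (default 1.5) and the unadjusted p-value is at most `p_cut`
(default 0.05). The strict/inclusive asymmetry is deliberate and tested:
`|FC| = 1.5` exactly fails, `p = 0.05` exactly passes.

Probes collapse to gene symbols with an any-probe-passes rule **per
direction**. Because array platforms carry several probe sets per gene and
those can disagree, one gene can legitimately end up in both the over- and
under-expressed list; such *dual-direction* genes are kept in both lists and
their count is surfaced in every report rather than silently resolved.
Symbols are normalized (trimmed, upper-cased) and `///`-joined multi-symbol
annotations contribute every symbol. No multiple-testing correction is
applied by default, matching the unadjusted-p filter convention of the
vendor consoles this emulates; the within-condition statistic of those
consoles is unspecified, and Welch on log2 values is used as a standard,
reproducible choice.

Zero-variance rows are edge cases a plain Welch formula leaves undefined:
with identical values in both conditions the p-value is NaN (can never
pass); with zero variance but a nonzero shift the evidence is exact and p is
set to 0.

### Pairwise overlap: Jaccard with a size-matched permutation null

For lists `a`, `b` over a background universe of `N` genes the observed
statistic is the Jaccard index `J = |a∩b| / |a∪b|` (0 when both sets are
empty). Its null distribution is obtained by drawing `n_perm` (default
10,000) uniform subsets of size `|a|` from the universe — each draw is a
genuine subset via partial Fisher–Yates sampling without replacement, not a
shortcut through the intersection-count distribution — holding `b` fixed and
recomputing `J`. The result reports:

* `null_mean`, `null_sd` — moments of the permuted values (`null_sd` is the
  population SD: the permuted collection *is* the null distribution, so no
  n−1 correction applies and z is reproducible bit for bit);
* `z = (J_obs − null_mean) / null_sd`, NaN when the null is degenerate;
* an add-one empirical p-value `(r + 1)/(n_perm + 1)` with `r` the number of
  permuted values ≥ observed (ties inclusive), so p is never 0 and never
  overstates significance at finite `n_perm`.

Which list is size-matched and redrawn is a parameter (`randomize =
"a" | "b" | "both"`, default `"a"`): conventionally the focal experiment is
placed first and only its list is randomized. The default decision rule is
`empirical_p < 0.05`; z is reported alongside but not used alone, since the
Jaccard index is bounded and its null need not be normal.

`analytic_null_moments` provides the exact mean and SD of `J` under
independence: the intersection size `X` of two uniform fixed-size subsets is
Hypergeometric(N, |a|, |b|) and `J = X/(|a|+|b|−X)` is a monotone function
of `X`, so the moments are finite sums over the hypergeometric support. This
closed form is used as an independent check on the permutation machinery
(and is itself validated against full enumeration at N = 10).

### Exact k-way intersection statistics

Under the null that each of `k` lists is an independent uniform draw of its
size `n_i` from the universe, the distribution of the k-way intersection
size follows by iterated hypergeometric convolution: `X₂ ~
Hypergeometric(N, n₁, n₂)`, and for each further list
`P(X_i = x) = Σ_m P(X_{i−1} = m) · HypergeomPmf(x; N, m, n_i)`.
The support of the running intersection after `i` lists is
`0..min(n₁..n_i)` and is truncated only as each list is folded in. The
reported `exact_p = P(X ≥ observed)` is an exact tail probability, with
`expected = N·∏(n_i/N)` and fold enrichment alongside.

Numerics: the k = 2 base case is the closed-form hypergeometric pmf
bit for bit. Transition grids for k ≥ 3 are evaluated from the
binomial-coefficient form via `gammaln` (the elementwise library pmf is
exact but orders of magnitude too slow on the ~800×800 grids that arise at
a 20,000-gene universe). The convolution runs in linear space with a total-
mass guard (|Σpmf − 1| ≤ 1e-9); if mass is lost to underflow, or the tail
sums to 0 in linear space, the computation is redone in log space with
`logsumexp`. At study scale the tails of interest are ~1e-29 to 1e-37 and
remain well inside double precision.

### The synthetic study generator

The generator emulates the inputs of a multi-experiment microarray overlap
study with known truth:

* **Universe** — `N` unique synthetic symbols (default study scale
  N = 20,000, the order of genes annotated on a human expression array).
* **Experiments** — per experiment, `n_over`/`n_under` planted DEGs
  (study scale: 1687/1027 and 800/900), a mean absolute planted shift
  `effect_log2fc` (default 1.0 log2 units, i.e. linear FC 2 — a clear but
  not extreme effect above the 1.5 cut), within-group noise SD `sigma`
  (default 0.25 log2 units, a typical array replicate SD), and
  `replicates_per_condition` (default 3, the usual minimal array design).
* **Planted intersections** — `shared_blocks` pin an exact core of shared
  genes per (experiment, direction) combination, drawn from a global pool so
  distinct blocks never collide; remaining slots are filled uniformly from
  genes unused by that experiment. Chance co-occurrence among fills is
  *allowed* (as in real experiments, and necessary for the null to be
  honest); realized intersections therefore equal the planted core plus a
  hypergeometric-scale number of chance extras. A `disjoint_fill` switch
  removes the chance extras when exact disjointness is wanted.
* **Dual-direction genes** — `dual_direction_count` genes of one experiment
  get two probe rows with the same symbol and opposite planted directions,
  reproducing the platform artifact by its actual mechanism; they occupy one
  slot in each directional list, so list sizes always equal the design.
* **Expression matrices** — baseline log2 intensities are normal
  (lognormal on the linear scale) with mean 7.0 and SD 1.5 (typical array
  intensity location/spread); planted rows are shifted by ±`effect_log2fc`
  in the treatment columns; all cells carry iid N(0, σ²) noise.

Seeding: one master seed; every stage, experiment, block and comparison
derives its own stream via a SHA-256 hash of (seed, label path), so adding
an experiment or reordering a config never perturbs other streams, and
identical designs are bit-identical.

What the generator does **not** model: probe-level summarization and
normalization, inter-array batch effects, intensity-dependent variance,
correlated gene programs, or RNA-seq counts. Passing tests therefore
demonstrate the statistics and plumbing are correct on clean planted
structure — not that any particular biological dataset meets the
independence assumptions of the nulls.

## Choices of problem size in the test suite

The statistical acceptance checks fix their own scales; these are the
package's choices of representative conditions:

* *Exactness*: full enumeration over all subset placements is feasible only
  for tiny universes; the exact test is compared to enumeration at N ≤ 10,
  k ≤ 3 (tolerance 1e-12) and to the closed-form hypergeometric for every
  size pair at N ∈ {5, 8, 10} (exact equality).
* *Permutation/analytic agreement*: study scale (N = 20,000, sizes
  1687/800), 10,000 permutations, 100 fixed seeds; the null mean must fall
  within 3·(analytic SD/√n_perm) in ≥ 99 runs.
* *Type-I calibration*: 1,000 independent generator-drawn null pairs at
  N = 10,000 with |a| = |b| = 1,000 and n_perm = 199. The sizes were chosen
  from a discreteness analysis done before running the test: with the
  add-one correction the attainable rejection rate at nominal 0.05 is
  E[P(Binom(n_perm, q(X)) ≤ ⌊0.05·(n_perm+1)⌋−1)] ≈ 0.045, and the pmf step
  of the hypergeometric tail near the 5% point (~0.012 at these sizes)
  keeps every attainable rate inside the exact binomial 99% interval
  around 0.05 for 1,000 trials (≈ [0.033, 0.069]). Smaller list sizes make
  the statistic too discrete for the interval; these are the smallest
  comfortable sizes.
* *Planted recovery and determinism*: the full study-shaped design
  (three experiments, planted pairwise cores 61/53 and 367/388 containing
  triple cores 23/28, 18 dual-direction genes) with 2,000 permutations per
  comparison in the determinism check and 10,000 in the acceptance script.

## Known limitations

* The permutation null size-matches exactly the list being randomized; a
  null that preserves expression-level strata (conditioning on intensity or
  variance) is out of scope.
* The exact multi-set test assumes each list is an independent uniform draw
  of its observed size; gene–gene correlation or selection coupling between
  experiments violates that and is not modeled.
* `ingest_geo2r` trusts the export's log fold changes and p-values; it does
  not recompute statistics from raw data, and exact reproduction of counts
  derived from vendor-console statistics is not expected.
* With `disjoint_fill`, fills are drawn sequentially across experiments, so
  per-experiment stream independence (the add-an-experiment guarantee) does
  not hold in that mode.
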