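# Methods

## Model and assumptions

Nucleotide evolution is a reversible continuous-time Markov process
(HKY85: transition/transversion ratio κ, stationary frequencies
π_A..π_T). The instantaneous rate matrix is normalised so that
−Σ_a π_a Q_aa = 1, i.e. one unit of branch length equals one expected
substitution per site at stationarity; this is what makes the neutral
tree's branch lengths (estimated elsewhere, e.g. from fourfold
degenerate sites) directly interpretable as per-site neutral rates.
Transition matrices P(t) = exp(Qt) are computed from the symmetrised
eigendecomposition (π^½ Q π^−½ is symmetric for reversible models),
which is numerically stable and vectorises over branch lengths;
P(0) is forced to the exact identity.

Likelihoods are root-invariant under reversibility; the tree is used
as rooted as given, and a basal trifurcation is accepted. Per-column
inference assumes columns are independent and the only free parameter
is a single rescaling r ≥ 0 multiplying every branch — deliberately
*not* one parameter per branch, which would mean estimating k
parameters from k nucleotides.

Gap handling: species gapped at a column are projected out of the
tree (degree-2 nodes collapsed, lengths summed, the projected root at
the MRCA of the remaining leaves). Ambiguity codes (N and other IUPAC
letters) are treated exactly like gaps and projected out rather than
marginalised over; this keeps the neutral-rate definition (sum of
retained branch lengths) consistent with what the likelihood actually
conditions on. Columns with fewer than 3 ungapped species carry no
information about rates and are emitted as an all-zero unscored
sentinel (the `scored` flag, not the zeros, is authoritative; the
two-column rates file writes `0.000000\t0.000000` for them, so a
neutral rate of exactly 0 marks an unscored line on re-reading).

## Rate estimation

The log-likelihood is maximised over r ∈ [0, 3]. The cap at 3 bounds
RS in [−2n, +n]; when the interior optimum would exceed the cap the
estimate is clamped to 3 rather than re-optimised. The scalar code
path (`estimate_rate`) uses bounded Brent with absolute tolerance
1e-4 on r — scores are later discretized to 0.1 RS, so finer
precision is wasted. The vectorised path (`score_alignment`) runs a
fixed-iteration golden-section search on batches of columns (32
iterations, interval width ≈ 3·0.618³² ≈ 1e-6) and agrees with the
scalar path to ~2e-5 in r; both explicitly evaluate the endpoints
r = 0 and r = 3 and snap to whichever is at least as good as the
interior point, so invariant columns report exactly r = 0 and
maximally discordant columns exactly r = 3. L(0) = 0 for any
non-invariant column and is handled as −∞ in log space. Columns are
de-duplicated by (gap pattern, nucleotide pattern) before fitting,
and tree projections are cached per gap pattern.

## Null model and p-values

Scores are discretized to the nearest multiple of t = 0.1 RS,
rounding halves away from zero. A region's null histogram is built
from its own discretized scores with three adjustments:

- **Long shallow runs** (≥ 10 consecutive positions with neutral rate
  < 0.5 substitutions/site) are excluded outright — they carry almost
  no rate information and would skew the distribution.
- **Remaining shallow positions** are penalised by
  min(0.5·(0.5 − n), 0.5) RS. The penalty is applied consistently to
  both the histogram *and* the candidate scores: penalising only the
  null would make shallow-heavy segments look more significant, the
  opposite of the intent. Its magnitude (half the shortfall below the
  cutoff) is a design choice; only "small" is prescribed.
- **Clearly constrained intervals** found by a preliminary pass of
  the full algorithm with false-positive cutoff 0 (accept only
  elements more significant than anything seen in any shuffle) are
  excluded, so strong signal does not contaminate the null. One
  preliminary round only; no iteration.

A pseudocount of 1 is added to every bin before normalisation so that
every representable score has positive probability. The bin range is
the observed (discretized) score range of the region rather than the
theoretical ±(2n_max, n_max) envelope: this keeps the histogram a
pure function of the score multiset, which in turn makes p-values
exactly invariant under a uniform additive shift of all scores (the
shift-invariance property the detector is supposed to have; a
theoretical envelope would break it through the prior mass, since n
does not shift with the scores).

P-values Pr(sum of L i.i.d. draws ≥ S) are computed by iterated
convolution of the single-position distribution (numpy `convolve`),
trimming bins whose probability underflows to exactly zero; results
are produced in one shared pass for all candidate lengths of a
region (real track plus shuffles). The DP is exact to float64; tails
below ~1e-308 underflow to 0. Where several candidates share p = 0
after underflow, their order is restored with a normal-approximation
z-score (S − Lμ)/(σ√L) computed from the histogram moments — without
this, the longest-element tie-break would absorb arbitrary neutral
flanks into extremely strong elements.

## Candidates and selection

Every candidate element starts at the first position of a maximal run
of non-negative (discretized, shallow-penalised) scores and ends at
the last position of such a run; it may span negative or unscored
stretches in between. This is the "cannot be extended further" rule
read as: the positions immediately outside both endpoints are
negative, unscored, or region edges. Length is bounded to [4, 2000]
and candidates must score at least q·L·median(n) with q = 0.05 RS per
neutral substitution — a permissive linear pruning rule; the
threshold's exact form is a design choice and is configurable. Tests
confirm the default pruning never removes a candidate that would
survive final selection at default settings (the accepted elements'
score/length ratios sit far above it).

Selection is greedy by increasing p-value (ties: longer element
first, then leftmost), discarding candidates that overlap an accepted
element. The expected number of false predictions at p-value
threshold p is the mean, across 5 independently permuted copies of
the region, of the number of elements the identical greedy machinery
accepts in the permutation at thresholds ≤ p. Permutations shuffle
the (n, r, RS) triples of all scored positions uniformly, freezing
long shallow runs and unscored positions in place; each permuted
track is scored against the *real* region's histogram (a permutation
has the same score multiset, hence the same null). Selection stops
the first time expected-false/accepted exceeds the cutoff (default
0.05, measured in predictions). The cutoff is applied per region and
expectations are pooled across regions.

The detection curve reports B(c) (bases in predictions at cutoff c),
F(c) (expected false bases at the corresponding stopping threshold)
and B*(c) = B − F over a cutoff grid; max_c B*(c) estimates the
total detectable constrained bases. B(c) is non-decreasing by
construction (a larger cutoff can only move the first-exceedance
stopping point later).

Long tracks are tiled into regions of ~2 Mb, splitting inside the
longest unscored run (minimum length 10, reusing the shallow-run
default) near each target boundary and at the exact multiple when no
such run exists; elements never span region boundaries.

## Randomness

A single integer seed governs a run. Per-region, per-pass,
per-shuffle streams are derived deterministically through numpy
`SeedSequence` spawn keys, so results are bit-for-bit reproducible
and independent of evaluation order.

## The simulator

`simulate_alignment` draws columns i.i.d.: root base from the
stationary frequencies, then descent along each branch with
P(r·branch length), where r follows a per-column profile (neutral
background, planted constrained blocks, optionally a 3-periodic
codon pattern). Gaps are injected independently per species and
column (default rate 0.02, reference never gapped). The default tree
is a 16-leaf balanced phylogeny with equal branch lengths summing to
5.8 substitutions per neutral site, matching the phylogenetic scope
of a deep mammalian alignment.

What the simulator does *not* emulate: autocorrelated gap/indel
structure, alignment error, lineage-specific rate variation,
context-dependent substitution, and heterogeneous neutral rates along
the sequence. Passing tests therefore demonstrate correctness of the
estimation and detection machinery under the model's own assumptions,
not robustness to real-data misalignment artefacts.

## Problem sizes and observed behaviour

The test suite and the acceptance script use 100 kb tracks for
null-calibration and planted-recovery studies, 2000 columns per
setting for rate recovery, and 20 kb for the codon-periodicity study;
these sizes give tight statistics (e.g. ±0.015 standard error on a
mean r̂ at 2000 columns) at interactive runtimes.

One known bias is documented rather than hidden: the per-column ML
estimate r̂ is right-skewed, so its *mean* across neutral columns
(true r = 1) sits near 1.13 on the default tree even though the
median is ~1.00 and the pooled likelihood across columns peaks at
r = 1.000. This is intrinsic to single-column maximum likelihood
with ~16 observations, not an optimizer artefact (the pruning
likelihood matches exhaustive enumeration to 1e-15 and batch and
scalar optimizers agree to 2e-5). In practice the element detector is
self-calibrating against this skew because the null histogram is
built from the same estimator's output.

## Limitations

- P-values assume score homogeneity within a region and independence
  across sites; both fail to some degree on real genomes.
- The greedy tie-break favours longer elements at equal significance.
- Only HKY85 ships, though the model interface (anything providing
  stationary frequencies and P(t)) is pluggable.
- Indels are not modelled; lineage-specific deletions reduce n rather
  than penalising the score.
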