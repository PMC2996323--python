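"""Constrained-element detection from rejected-substitution score tracks.

The null model for a region is the empirical distribution of its own
discretized RS scores, minus long runs of shallow positions (too few
aligned species to say much) and minus clearly constrained intervals
found in a preliminary pass; a uniform prior guarantees every bin has
positive probability.  The p-value of a candidate element of length L
and score S is the probability that L i.i.d. draws from that null sum
to at least S, computed exactly by iterated convolution of the
discretized distribution.

Candidates start and end at positions that terminate maximal runs of
non-negative scores, may span intervening negative stretches, and are
pruned by a permissive length/score threshold.  Final predictions are
selected greedily in order of increasing p-value, discarding overlaps,
until the shuffle-estimated false-positive fraction among accepted
predictions exceeds the chosen cutoff.  False positives are estimated
by running the identical machinery on column-permuted tracks.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .rate_scoring import ScoredTrack

__all__ = [
    "DetectorParams", "ScoreHistogram", "CandidateElement", "CandidateSet",
    "ConstrainedElement", "DetectionCurve", "DetectionResult",
    "build_histogram", "pvalue", "enumerate_candidates", "select_elements",
    "permute_track", "estimate_fpr", "detect_elements", "detection_curve",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunable parameters of the element detector.

    Lengths are in reference positions, rates in substitutions/site,
    scores in rejected substitutions (RS).
    """

    min_length: int = 4
    max_length: int = 2000
    shallow_cutoff: float = 0.5      # neutral rate below which a site is shallow
    shallow_run: int = 10            # run length of shallow sites excluded outright
    shallow_penalty: float = 0.5     # cap on the per-site shallow score penalty
    tolerance: float = 0.1           # RS discretization step t
    prior_weight: float = 1.0        # pseudocount per histogram bin
    threshold_q: float = 0.05        # candidate pruning: S >= q * L * median(n)
    fp_cutoff: float = 0.05          # false positives per prediction at stop
    n_shuffles: int = 5
    chunk_size: int = 2_000_000      # region target size


def discretize(x, t: float) -> np.ndarray:
    """Round to the nearest multiple of `t`, halves away from zero."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) / t + 0.5)).astype(np.int64)


def _run_lengths(mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Starts and (exclusive) ends of runs of True in `mask`."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    d = np.diff(m.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if m[0]:
        starts = np.concatenate([[0], starts])
    if m[-1]:
        ends = np.concatenate([ends, [m.size]])
    return starts.astype(np.int64), ends.astype(np.int64)


def adjusted_scores(track: ScoredTrack, params: DetectorParams = DetectorParams()
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Shallow-penalised scores and the histogram inclusion mask.

    Returns ``(adj, include)`` where `adj` applies the per-site shallow
    penalty min(0.5*(cutoff - n), penalty cap) to shallow positions
    outside long shallow runs, and `include` is True for scored
    positions outside long shallow runs (the histogram population).
    The penalised scores are used consistently for both the null
    histogram and candidate scoring.
    """
    shallow = track.scored & (track.neutral_rate < params.shallow_cutoff)
    long_mask = np.zeros(len(track), dtype=bool)
    starts, ends = _run_lengths(shallow)
    for s, e in zip(starts, ends):
        if e - s >= params.shallow_run:
            long_mask[s:e] = True
    pen = np.minimum(0.5 * (params.shallow_cutoff - track.neutral_rate),
                     params.shallow_penalty)
    adj = np.where(track.scored, track.rs, 0.0)
    adj = np.where(shallow & ~long_mask, adj - pen, adj)
    include = track.scored & ~long_mask
    return adj, include


def _intervals_to_mask(intervals: Iterable[Tuple[int, int]], n: int
                       ) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[max(s, 0):min(e, n)] = True
    return mask


class ScoreHistogram:
    """Discretized null distribution of per-position RS scores.

    Bins are integer multiples of the tolerance `t` spanning the
    observed score range; a pseudocount of `prior_weight` on every bin
    guarantees strictly positive probabilities.  Provides exact tail
    probabilities of sums of L i.i.d. draws via iterated convolution.
    """

    def __init__(self, counts: np.ndarray, offset: int, t: float,
                 prior_weight: float = 1.0):
        if t <= 0:
            raise ValueError("tolerance t must be positive")
        counts = np.asarray(counts, dtype=float)
        if counts.size == 0:
            raise ValueError("histogram needs at least one bin")
        probs = counts + prior_weight
        total = probs.sum()
        if not total > 0:
            raise ValueError("histogram has no mass")
        self.t = float(t)
        self.offset = int(offset)            # index of the lowest bin
        self.probs = probs / total
        # cached DP state: distribution of the sum of `l` draws
        self._dp_len = 1
        self._dp_offset = self.offset
        self._dp = self.probs.copy()

    @classmethod
    def from_indices(cls, idx: np.ndarray, t: float,
                     prior_weight: float = 1.0) -> "ScoreHistogram":
        idx = np.asarray(idx, dtype=np.int64)
        if idx.size == 0:
            raise ValueError("no scores to build a histogram from")
        lo, hi = int(idx.min()), int(idx.max())
        counts = np.bincount(idx - lo, minlength=hi - lo + 1).astype(float)
        return cls(counts, lo, t, prior_weight)

    # -- summary statistics (index units) -------------------------------
    @property
    def bin_values(self) -> np.ndarray:
        """RS value of each bin."""
        return (self.offset + np.arange(len(self.probs))) * self.t

    @property
    def mean_index(self) -> float:
        return float(self.probs @ (self.offset + np.arange(len(self.probs))))

    @property
    def var_index(self) -> float:
        vals = self.offset + np.arange(len(self.probs))
        return float(self.probs @ (vals - self.mean_index) ** 2)

    # -- dynamic programming over sums ----------------------------------
    def _reset_dp(self):
        self._dp_len = 1
        self._dp_offset = self.offset
        self._dp = self.probs.copy()

    def _advance_dp(self):
        conv = np.convolve(self._dp, self.probs)
        offset = self._dp_offset + self.offset
        # trim bins that underflowed to exactly zero at the extremes
        nz = np.nonzero(conv)[0]
        conv = conv[nz[0]:nz[-1] + 1]
        offset += int(nz[0])
        self._dp = conv
        self._dp_offset = offset
        self._dp_len += 1

    def tail_pvalues(self, lengths: np.ndarray, score_idx: np.ndarray
                     ) -> np.ndarray:
        """Pr(sum of L draws >= S) for paired arrays of (L, S-index)."""
        lengths = np.asarray(lengths, dtype=np.int64)
        score_idx = np.asarray(score_idx, dtype=np.int64)
        if lengths.shape != score_idx.shape:
            raise ValueError("lengths and scores must pair up")
        out = np.empty(len(lengths), dtype=float)
        if len(lengths) == 0:
            return out
        if np.any(lengths < 1):
            raise ValueError("element length must be >= 1")
        order = np.argsort(lengths, kind="stable")
        if lengths[order[0]] < self._dp_len:
            self._reset_dp()
        i = 0
        while i < len(order):
            want = lengths[order[i]]
            while self._dp_len < want:
                self._advance_dp()
            j = i
            while j < len(order) and lengths[order[j]] == want:
                j += 1
            # summed from the extreme tail inward for accuracy
            rev_cum = np.cumsum(self._dp[::-1])
            sel = order[i:j]
            pos = score_idx[sel] - self._dp_offset
            n = len(self._dp)
            # tail from bin `pos` upward = rev_cum[n - 1 - pos]
            tails = np.where(
                pos <= 0, 1.0,
                rev_cum[np.clip(n - 1 - pos, 0, n - 1)] * (pos < n))
            out[sel] = np.minimum(tails, 1.0)
            i = j
        return out

    def pvalue(self, length: int, score: float) -> float:
        """Pr(sum of `length` draws >= `score`), score in RS units."""
        k = int(discretize(score, self.t))
        return float(self.tail_pvalues(np.array([length]), np.array([k]))[0])


def build_histogram(region_track: ScoredTrack,
                    shallow_cutoff: float = 0.5, shallow_run: int = 10,
                    penalty: float = 0.5,
                    excluded: Iterable[Tuple[int, int]] = (),
                    tolerance: float = 0.1,
                    prior_weight: float = 1.0) -> ScoreHistogram:
    """Null score histogram for a region.

    Excludes long runs of shallow positions and any `excluded`
    intervals (track-relative, half-open; typically constrained
    regions from the preliminary pass); remaining shallow positions
    contribute their penalised score.  Raises ValueError when nothing
    is left to build from.
    """
    params = DetectorParams(shallow_cutoff=shallow_cutoff,
                            shallow_run=shallow_run,
                            shallow_penalty=penalty, tolerance=tolerance,
                            prior_weight=prior_weight)
    adj, include = adjusted_scores(region_track, params)
    include = include & ~_intervals_to_mask(excluded, len(region_track))
    if not include.any():
        raise ValueError("all positions excluded; region unusable")
    idx = discretize(adj[include], tolerance)
    return ScoreHistogram.from_indices(idx, tolerance, prior_weight)


def pvalue(length: int, score: float, hist: ScoreHistogram) -> float:
    """P-value of an element of `length` positions and total RS `score`."""
    return hist.pvalue(length, score)


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateElement:
    """Candidate constrained interval (track coordinates, half-open)."""

    start: int
    end: int
    score: float
    pvalue: float

    @property
    def length(self) -> int:
        return self.end - self.start


class CandidateSet:
    """Array-backed collection of candidate elements for one region."""

    def __init__(self, starts, ends, score_idx, pvalues, zscores, t,
                 track_start: int = 0, chrom: str = "chr1"):
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.score_idx = np.asarray(score_idx, dtype=np.int64)
        self.pvalues = np.asarray(pvalues, dtype=float)
        self.zscores = np.asarray(zscores, dtype=float)
        self.t = t
        self.track_start = track_start
        self.chrom = chrom
        self._order: Optional[np.ndarray] = None

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def scores(self) -> np.ndarray:
        return self.score_idx * self.t

    def __len__(self) -> int:
        return len(self.starts)

    def __getitem__(self, i: int) -> CandidateElement:
        return CandidateElement(int(self.starts[i]), int(self.ends[i]),
                                float(self.score_idx[i] * self.t),
                                float(self.pvalues[i]))

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def selection_order(self) -> np.ndarray:
        """Greedy processing order: p-value ascending; ties broken by a
        normal-approximation significance score where p underflowed to
        zero, then longer-first, then leftmost."""
        if self._order is None:
            z_tie = np.where(self.pvalues == 0.0, self.zscores, 0.0)
            self._order = np.lexsort(
                (self.starts, -self.lengths, -z_tie, self.pvalues))
        return self._order


def _default_threshold(q: float):
    def fn(length, median_n):
        return q * np.asarray(length) * median_n
    return fn


def enumerate_candidates(region_track: ScoredTrack, min_length: int = 4,
                         max_length: int = 2000,
                         hist: Optional[ScoreHistogram] = None,
                         threshold_fn: Optional[Callable] = None,
                         params: DetectorParams = DetectorParams(),
                         assign_pvalues: bool = True) -> CandidateSet:
    """Enumerate candidate constrained elements for a region.

    Candidates run from the start of any maximal run of non-negative
    (discretized, shallow-penalised) scores to the end of any such
    run, possibly spanning negative stretches in between; length is
    bounded by [min_length, max_length] and the summed score must meet
    ``threshold_fn(length, median neutral rate)``.
    """
    if min_length < 1 or max_length < min_length:
        raise ValueError("need 1 <= min_length <= max_length")
    t = params.tolerance
    if hist is None and assign_pvalues:
        hist = build_histogram(
            region_track, params.shallow_cutoff, params.shallow_run,
            params.shallow_penalty, (), t, params.prior_weight)
    if threshold_fn is None:
        threshold_fn = _default_threshold(params.threshold_q)

    adj, _ = adjusted_scores(region_track, params)
    idx = discretize(adj, t)
    valid = region_track.scored
    contrib = np.where(valid, idx, 0)
    prefix = np.concatenate([[0], np.cumsum(contrib)])

    scored_n = region_track.neutral_rate[valid]
    median_n = float(np.median(scored_n)) if scored_n.size else 0.0

    nonneg = valid & (idx >= 0)
    run_starts, run_ends = _run_lengths(nonneg)

    starts_all: List[np.ndarray] = []
    ends_all: List[np.ndarray] = []
    if len(run_starts):
        chunk = max(1, 2_000_000 // max(len(run_ends), 1))
        for ci in range(0, len(run_starts), chunk):
            s_chunk = run_starts[ci:ci + chunk]
            lo = np.searchsorted(run_ends, s_chunk + min_length, side="left")
            hi = np.searchsorted(run_ends, s_chunk + max_length, side="right")
            counts = hi - lo
            keep = counts > 0
            if not keep.any():
                continue
            s_chunk, lo, counts = s_chunk[keep], lo[keep], counts[keep]
            starts = np.repeat(s_chunk, counts)
            ends = run_ends[
                np.concatenate([np.arange(l, l + c)
                                for l, c in zip(lo, counts)])]
            lengths = ends - starts
            score_i = prefix[ends] - prefix[starts]
            ok = (score_i * t) >= threshold_fn(lengths, median_n)
            starts_all.append(starts[ok])
            ends_all.append(ends[ok])

    if starts_all:
        starts = np.concatenate(starts_all)
        ends = np.concatenate(ends_all)
    else:
        starts = np.empty(0, dtype=np.int64)
        ends = np.empty(0, dtype=np.int64)
    score_i = prefix[ends] - prefix[starts]
    lengths = ends - starts

    if hist is not None:
        mu, var = hist.mean_index, hist.var_index
        z = ((score_i - lengths * mu)
             / np.sqrt(np.maximum(lengths * var, 1e-300)))
    else:
        z = np.zeros(len(starts))
    pvals = np.full(len(starts), np.nan)
    cset = CandidateSet(starts, ends, score_i, pvals, z, t,
                        track_start=region_track.start,
                        chrom=region_track.chrom)
    if assign_pvalues and hist is not None and len(cset):
        cset.pvalues[:] = hist.tail_pvalues(lengths, score_i)
    return cset


# ---------------------------------------------------------------------------
# greedy selection with shuffle-based false-positive control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstrainedElement:
    """A reported constrained element (genome coordinates, half-open)."""

    chrom: str
    start: int
    end: int
    score: float
    pvalue: float
    rank: int

    @property
    def length(self) -> int:
        return self.end - self.start


class _Greedy:
    """Greedy non-overlapping acceptance over a sorted candidate set."""

    def __init__(self, cands: CandidateSet):
        self.cands = cands
        self.order = cands.selection_order()
        self.ptr = 0
        self.acc_starts: List[int] = []
        self.acc_ends: List[int] = []
        self.count = 0
        self.bases = 0

    def _overlaps(self, s: int, e: int) -> bool:
        i = bisect.bisect_right(self.acc_starts, s)
        if i > 0 and self.acc_ends[i - 1] > s:
            return True
        if i < len(self.acc_starts) and self.acc_starts[i] < e:
            return True
        return False

    def _accept(self, s: int, e: int) -> None:
        i = bisect.bisect_right(self.acc_starts, s)
        self.acc_starts.insert(i, s)
        self.acc_ends.insert(i, e)
        self.count += 1
        self.bases += e - s

    def advance(self, p_max: float) -> None:
        """Greedily process all candidates with p-value <= p_max."""
        c = self.cands
        while self.ptr < len(self.order):
            i = self.order[self.ptr]
            if c.pvalues[i] > p_max:
                break
            s, e = int(c.starts[i]), int(c.ends[i])
            if not self._overlaps(s, e):
                self._accept(s, e)
            self.ptr += 1


class _NullEnsemble:
    """Lazy greedy selection over shuffled-track candidate sets."""

    def __init__(self, shuffle_sets: Sequence[CandidateSet]):
        self.walkers = [_Greedy(cs) for cs in shuffle_sets]

    def stats_at(self, p: float) -> Tuple[float, float]:
        """Expected false (predictions, bases) at p-value threshold `p`."""
        if not self.walkers:
            return 0.0, 0.0
        for w in self.walkers:
            w.advance(p)
        k = len(self.walkers)
        return (sum(w.count for w in self.walkers) / k,
                sum(w.bases for w in self.walkers) / k)


@dataclass
class _WalkRecord:
    pvalue: float
    start: int
    end: int
    score: float
    cum_bases: int
    exp_false: float
    exp_false_bases: float
    fraction: float


def _greedy_walk(cands: CandidateSet,
                 fpr_fn: Optional[Callable[[float], Tuple[float, float]]],
                 cutoff_max: float) -> List[_WalkRecord]:
    """Walk candidates in significance order, accepting non-overlapping
    elements until the estimated false-positive fraction first exceeds
    `cutoff_max`.  Returns one record per accepted element."""
    sel = _Greedy(cands)
    records: List[_WalkRecord] = []
    order = cands.selection_order()
    for i in order:
        p = float(cands.pvalues[i])
        s, e = int(cands.starts[i]), int(cands.ends[i])
        if sel._overlaps(s, e):
            continue
        fc, fb = fpr_fn(p) if fpr_fn is not None else (0.0, 0.0)
        m = sel.count + 1
        frac = fc / m
        if frac > cutoff_max:
            break
        sel._accept(s, e)
        records.append(_WalkRecord(p, s, e, float(cands.score_idx[i] *
                                                  cands.t),
                                   sel.bases, fc, fb, frac))
    return records


def select_elements(candidates: CandidateSet,
                    fpr_estimator: Optional[Callable[[float],
                                                     Tuple[float, float]]],
                    fp_cutoff: float) -> List[ConstrainedElement]:
    """Greedy significance-ranked selection of non-overlapping elements.

    `fpr_estimator` maps a p-value threshold to (expected false
    predictions, expected false bases); selection stops when the
    estimated false fraction among accepted predictions first exceeds
    `fp_cutoff`.  Pass None to disable false-positive control.
    """
    records = _greedy_walk(candidates, fpr_estimator, fp_cutoff)
    off = candidates.track_start
    return [ConstrainedElement(candidates.chrom, off + r.start, off + r.end,
                               r.score, r.pvalue, rank)
            for rank, r in enumerate(records, start=1)]


# ---------------------------------------------------------------------------
# shuffled tracks and false-positive estimation
# ---------------------------------------------------------------------------

def permute_track(region_track: ScoredTrack, shallow_cutoff: float = 0.5,
                  shallow_run: int = 10, seed=0) -> ScoredTrack:
    """Uniformly permute scored positions, freezing long shallow runs.

    Positions inside runs of at least `shallow_run` consecutive
    shallow sites, and unscored positions, keep their coordinates; all
    other (neutral rate, rescaling, RS) triples are shuffled among
    themselves, preserving the multiset of scores.
    """
    rng = np.random.default_rng(seed)
    shallow = region_track.scored & (region_track.neutral_rate
                                     < shallow_cutoff)
    frozen = ~region_track.scored
    starts, ends = _run_lengths(shallow)
    for s, e in zip(starts, ends):
        if e - s >= shallow_run:
            frozen[s:e] = True
    movable = np.nonzero(~frozen)[0]
    perm = rng.permutation(len(movable))
    out = region_track.copy()
    for name in ("neutral_rate", "rescaling", "rs", "scored"):
        arr = getattr(out, name)
        arr[movable] = arr[movable[perm]]
    return out


def _spawn_seed(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                  spawn_key=tuple(int(k) for k in key))


@dataclass
class _RegionPrep:
    hist: ScoreHistogram
    real: CandidateSet
    shuffles: List[CandidateSet]
    excluded: List[Tuple[int, int]]


def _assign_pvalues_joint(hist: ScoreHistogram,
                          csets: Sequence[CandidateSet]) -> None:
    """One shared DP pass for the p-values of several candidate sets."""
    lengths = np.concatenate([cs.lengths for cs in csets]) \
        if csets else np.empty(0, dtype=np.int64)
    scores = np.concatenate([cs.score_idx for cs in csets]) \
        if csets else np.empty(0, dtype=np.int64)
    if len(lengths) == 0:
        return
    pvals = hist.tail_pvalues(lengths, scores)
    mu, var = hist.mean_index, hist.var_index
    pos = 0
    for cs in csets:
        k = len(cs)
        cs.pvalues[:] = pvals[pos:pos + k]
        cs.zscores[:] = ((cs.score_idx - cs.lengths * mu)
                         / np.sqrt(np.maximum(cs.lengths * var, 1e-300)))
        cs._order = None
        pos += k


def _enumerate_raw(track: ScoredTrack, params: DetectorParams) -> CandidateSet:
    return enumerate_candidates(track, params.min_length, params.max_length,
                                hist=None, threshold_fn=None, params=params,
                                assign_pvalues=False)


def _prepare_region(rtrack: ScoredTrack, params: DetectorParams, seed: int,
                    region_index: int) -> _RegionPrep:
    """Preliminary pass (fp cutoff 0) then final histogram and candidates."""

    def shuffled(pass_idx: int) -> List[ScoredTrack]:
        return [permute_track(rtrack, params.shallow_cutoff,
                              params.shallow_run,
                              seed=_spawn_seed(seed, region_index,
                                               pass_idx, i))
                for i in range(params.n_shuffles)]

    hist0 = build_histogram(rtrack, params.shallow_cutoff,
                            params.shallow_run, params.shallow_penalty, (),
                            params.tolerance, params.prior_weight)
    real0 = _enumerate_raw(rtrack, params)
    shuf0 = [_enumerate_raw(s, params) for s in shuffled(0)]
    _assign_pvalues_joint(hist0, [real0] + shuf0)
    prelim = _greedy_walk(real0, _NullEnsemble(shuf0).stats_at,
                          cutoff_max=0.0)
    excluded = [(r.start, r.end) for r in prelim]

    try:
        hist1 = build_histogram(rtrack, params.shallow_cutoff,
                                params.shallow_run, params.shallow_penalty,
                                excluded, params.tolerance,
                                params.prior_weight)
    except ValueError:
        hist1 = hist0  # everything constrained: keep the preliminary null
    real1 = _enumerate_raw(rtrack, params)
    shuf1 = [_enumerate_raw(s, params) for s in shuffled(1)]
    _assign_pvalues_joint(hist1, [real1] + shuf1)
    return _RegionPrep(hist1, real1, shuf1, excluded)


def estimate_fpr(region_track: ScoredTrack, n_shuffles: int = 5, seed=0,
                 params: DetectorParams = DetectorParams(),
                 thresholds: Optional[Sequence[float]] = None
                 ) -> Dict[float, Tuple[float, float]]:
    """Expected false (predictions, bases) per p-value threshold.

    Runs the full candidate + greedy-selection machinery on
    `n_shuffles` permuted copies of the region (after the preliminary
    constrained-region exclusion) and averages.  By default the
    thresholds are the p-values at which the expectation changes.
    """
    params = replace(params, n_shuffles=n_shuffles)
    prep = _prepare_region(region_track, params, int(seed), 0)
    if thresholds is None:
        thr: List[float] = []
        for cs in prep.shuffles:
            records = _greedy_walk(cs, None, np.inf)
            thr.extend(r.pvalue for r in records)
        thresholds = sorted(set(thr)) or [1.0]
    ensemble = _NullEnsemble(prep.shuffles)
    out: Dict[float, Tuple[float, float]] = {}
    for p in sorted(thresholds):
        out[float(p)] = ensemble.stats_at(float(p))
    return out


# ---------------------------------------------------------------------------
# full detection pipeline
# ---------------------------------------------------------------------------

@dataclass
class DetectionCurve:
    """B(c), F(c) and B*(c) = B - F over a false-positive cutoff grid."""

    cutoffs: np.ndarray
    predicted_bases: np.ndarray
    false_bases: np.ndarray

    @property
    def adjusted_bases(self) -> np.ndarray:
        return self.predicted_bases - self.false_bases

    @property
    def max_adjusted(self) -> float:
        return float(self.adjusted_bases.max()) if len(self.cutoffs) else 0.0

    @property
    def argmax_cutoff(self) -> float:
        if not len(self.cutoffs):
            return float("nan")
        return float(self.cutoffs[int(np.argmax(self.adjusted_bases))])


@dataclass
class DetectionResult:
    """Output of a full detection run."""

    elements: List[ConstrainedElement]
    expected_false_elements: float
    expected_false_bases: float
    fpr_rows: List[Tuple[float, float, float, int]]
    curve: Optional[DetectionCurve] = None

    @property
    def predicted_bases(self) -> int:
        return sum(e.length for e in self.elements)

    @property
    def nucleotide_fpr(self) -> float:
        b = self.predicted_bases
        return self.expected_false_bases / b if b else 0.0


def detect_elements(track: ScoredTrack,
                    params: DetectorParams = DetectorParams(), seed=0,
                    curve_grid: Optional[Sequence[float]] = None
                    ) -> DetectionResult:
    """Run the two-stage detector over a whole scored track.

    The track is tiled into regions; each region gets its own null
    histogram (after a preliminary constrained-region exclusion pass)
    and its own shuffle ensemble; elements never span region
    boundaries.  The false-positive cutoff is applied per region and
    the expectations are pooled.
    """
    from .alignment_io import chunk_regions

    seed = int(seed)
    grid = np.asarray(sorted(curve_grid), dtype=float) \
        if curve_grid is not None else None
    cutoff_max = params.fp_cutoff if grid is None \
        else max(params.fp_cutoff, float(grid.max()))

    regions = chunk_regions(track, params.chunk_size, params.shallow_run)
    all_records: List[Tuple[int, List[_WalkRecord]]] = []  # (region off, recs)
    chrom = track.chrom
    for ridx, region in enumerate(regions):
        if not region.track.scored.any():
            continue
        prep = _prepare_region(region.track, params, seed, ridx)
        records = _greedy_walk(prep.real, _NullEnsemble(prep.shuffles).stats_at,
                               cutoff_max)
        all_records.append((region.start, records))

    # per-region stop at the requested cutoff, then pool
    elements: List[ConstrainedElement] = []
    fpr_rows: List[Tuple[float, float, float, int]] = []
    exp_false = 0.0
    exp_false_bases = 0.0
    for off, records in all_records:
        stop = len(records)
        for k, r in enumerate(records):
            if r.fraction > params.fp_cutoff:
                stop = k
                break
        kept = records[:stop]
        for r in kept:
            elements.append(ConstrainedElement(
                chrom, off + r.start, off + r.end, r.score, r.pvalue, 0))
        if kept:
            exp_false += kept[-1].exp_false
            exp_false_bases += kept[-1].exp_false_bases
            for m, r in enumerate(kept, start=1):
                fpr_rows.append((r.pvalue, r.exp_false, r.exp_false_bases, m))

    elements.sort(key=lambda e: (e.pvalue, -(e.end - e.start), e.start))
    elements = [replace(e, rank=i) for i, e in enumerate(elements, start=1)]

    curve = None
    if grid is not None:
        b = np.zeros(len(grid))
        f = np.zeros(len(grid))
        for off, records in all_records:
            fractions = np.array([r.fraction for r in records])
            cum_bases = np.array([r.cum_bases for r in records])
            fbases = np.array([r.exp_false_bases for r in records])
            for gi, c in enumerate(grid):
                viol = np.nonzero(fractions > c)[0]
                stop = int(viol[0]) if len(viol) else len(records)
                if stop > 0:
                    b[gi] += cum_bases[stop - 1]
                    f[gi] += fbases[stop - 1]
        curve = DetectionCurve(grid, b, f)

    return DetectionResult(elements, exp_false, exp_false_bases,
                           fpr_rows, curve)


def detection_curve(region_track: ScoredTrack,
                    cutoff_grid: Sequence[float],
                    params: DetectorParams = DetectorParams(),
                    seed=0) -> DetectionCurve:
    """Predicted and false-positive-adjusted bases over a cutoff grid.

    ``max_c B*(c)`` estimates the total constrained bases detectable
    in the region with this methodology.
    """
    grid = np.asarray(cutoff_grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 1):
        raise ValueError("cutoff grid must lie in [0, 1]")
    return detect_elements(region_track, params, seed,
                           curve_grid=grid).curve
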