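"""Per-column evolutionary rate estimation and rejected-substitution scores.

Each alignment column is scored by fitting, by maximum likelihood, a
single rescaling factor r applied uniformly to every branch of the
neutral tree (after projecting out species that are gapped at the
column).  With n the neutral rate of the projected tree (its total
branch length), the estimated rate is r*n and the rejected
substitutions score is

    RS = n - r*n = n * (1 - r),

positive where substitutions were "rejected" (constraint) and negative
where there is a substitution surplus.  r is capped at 3, so RS ranges
between -2n and +n.  Columns with fewer than 3 ungapped species are
not scored.

The likelihood Pr(column | tree scaled by r) is computed by the
standard postorder pruning recursion, which is linear in the number of
species.  `score_alignment` evaluates many columns at once with a
vectorised bounded golden-section search; `estimate_rate` handles a
single column with Brent's method and is the reference code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize_scalar

from .phylo_model import BASE_INDEX, NeutralTree, SubstitutionModel

GAP_CODE = 4  #: internal code for gap / ambiguous / missing
R_MAX = 3.0   #: cap on the maximum-likelihood rescaling factor

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def symbol_to_code(symbol: str) -> int:
    """Map a column symbol to 0..3 for A,C,G,T; anything else is missing.

    Ambiguity codes (N and other IUPAC letters) are treated like gaps
    and projected out of the tree rather than marginalised over.
    """
    return BASE_INDEX.get(symbol.upper(), GAP_CODE)


@dataclass(frozen=True)
class AlignmentColumn:
    """One alignment column: species -> symbol, at a reference position."""

    bases: Dict[str, str]
    position: int = 0

    def present_codes(self) -> Dict[str, int]:
        """Species carrying an unambiguous nucleotide, as integer codes."""
        out = {}
        for sp, sym in self.bases.items():
            code = symbol_to_code(sym)
            if code != GAP_CODE:
                out[sp] = code
        return out


@dataclass(frozen=True)
class PositionScore:
    """Score record for one reference position.

    When ``scored`` is False (fewer than 3 ungapped species) the
    numeric fields are a conventional all-zero sentinel and carry no
    information; the flag is authoritative.
    """

    neutral_rate: float
    rescaling: float
    rs_score: float
    scored: bool


@dataclass
class ScoredTrack:
    """Dense per-position score arrays over a reference interval."""

    neutral_rate: np.ndarray
    rescaling: np.ndarray
    rs: np.ndarray
    scored: np.ndarray
    chrom: str = "chr1"
    start: int = 0

    def __post_init__(self):
        n = len(self.rs)
        for name in ("neutral_rate", "rescaling", "scored"):
            if len(getattr(self, name)) != n:
                raise ValueError("track arrays must have equal length")

    def __len__(self) -> int:
        return len(self.rs)

    @property
    def end(self) -> int:
        return self.start + len(self)

    def slice(self, i: int, j: int) -> "ScoredTrack":
        """View of positions [i, j) (track-relative indices)."""
        return ScoredTrack(self.neutral_rate[i:j], self.rescaling[i:j],
                           self.rs[i:j], self.scored[i:j],
                           chrom=self.chrom, start=self.start + i)

    def copy(self) -> "ScoredTrack":
        return ScoredTrack(self.neutral_rate.copy(), self.rescaling.copy(),
                           self.rs.copy(), self.scored.copy(),
                           chrom=self.chrom, start=self.start)

    def __getitem__(self, i: int) -> PositionScore:
        return PositionScore(float(self.neutral_rate[i]),
                             float(self.rescaling[i]), float(self.rs[i]),
                             bool(self.scored[i]))

    @staticmethod
    def from_scores(scores: Sequence[PositionScore], chrom: str = "chr1",
                    start: int = 0) -> "ScoredTrack":
        n = np.array([s.neutral_rate for s in scores], dtype=float)
        r = np.array([s.rescaling for s in scores], dtype=float)
        rs = np.array([s.rs_score for s in scores], dtype=float)
        sc = np.array([s.scored for s in scores], dtype=bool)
        return ScoredTrack(n, r, rs, sc, chrom=chrom, start=start)


# ---------------------------------------------------------------------------
# single-column likelihood and rate estimation
# ---------------------------------------------------------------------------

def column_likelihood(column: Union[AlignmentColumn, Dict[str, str]],
                      tree: NeutralTree, model: SubstitutionModel,
                      r: float) -> float:
    """Pr(observed leaf nucleotides | tree with branches scaled by r).

    The column must cover exactly the tree's leaves with unambiguous
    nucleotides; gapped species are expected to have been projected
    out already.
    """
    if r < 0:
        raise ValueError("rescaling factor r must be non-negative")
    bases = column.bases if isinstance(column, AlignmentColumn) else column
    unknown = set(bases) - set(tree.leaf_ids)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    codes = {}
    for label in tree.leaf_ids:
        if label not in bases:
            raise ValueError(f"column missing species {label!r}")
        code = symbol_to_code(bases[label])
        if code == GAP_CODE:
            raise ValueError(
                f"column has gap/ambiguous base for {label!r}; project first")
        codes[label] = code

    partial: Dict[int, np.ndarray] = {}
    for node in range(tree.n_nodes):
        if tree.is_leaf(node):
            vec = np.zeros(4)
            vec[codes[tree.labels[node]]] = 1.0
            partial[node] = vec
        else:
            acc = np.ones(4)
            for child in tree.children[node]:
                p = model.transition_matrix(r * tree.lengths[child])
                acc = acc * (p @ partial[child])
            partial[node] = acc
    like = float(partial[tree.root] @ model.frequencies)
    return max(like, 0.0)


_UNSCORED = PositionScore(0.0, 0.0, 0.0, False)


def estimate_rate(column: Union[AlignmentColumn, Dict[str, str]],
                  tree: NeutralTree, model: SubstitutionModel,
                  xatol: float = 1e-4) -> PositionScore:
    """ML rescaling and RS score for one column.

    Gapped/ambiguous species are projected out of the tree; if fewer
    than 3 remain the unscored sentinel is returned.  Otherwise the
    log-likelihood is maximised over r in [0, 3] with bounded Brent,
    the boundaries themselves being checked explicitly so invariant
    columns report r = 0 and maximally discordant columns r = 3.
    """
    col = column if isinstance(column, AlignmentColumn) else \
        AlignmentColumn(dict(column))
    codes = col.present_codes()
    proj = tree.project(set(codes))
    if proj is None:
        return _UNSCORED
    n = proj.scope()
    sub = {sp: col.bases[sp] for sp in proj.leaf_ids}

    def negloglike(r: float) -> float:
        like = column_likelihood(sub, proj, model, r)
        if like <= 0.0:
            return np.inf
        return -np.log(like)

    res = minimize_scalar(negloglike, bounds=(0.0, R_MAX), method="bounded",
                          options={"xatol": xatol})
    r_hat = float(res.x)
    f_hat = float(res.fun)
    # snap to the boundary when it is at least as good as the interior point
    f_hi = negloglike(R_MAX)
    f_lo = negloglike(0.0)
    if f_hi <= f_hat + 1e-12:
        r_hat = R_MAX
    elif f_lo <= f_hat + 1e-12:
        r_hat = 0.0
    r_hat = min(max(r_hat, 0.0), R_MAX)
    return PositionScore(n, r_hat, n * (1.0 - r_hat), True)


# ---------------------------------------------------------------------------
# vectorised whole-alignment scoring
# ---------------------------------------------------------------------------

class _TreeKernel:
    """Flattened pruning machinery for one projected tree."""

    def __init__(self, tree: NeutralTree, model: SubstitutionModel):
        self.tree = tree
        self.model = model
        self.scope = tree.scope()
        self.leaf_order = [tree.leaf_ids[lab] for lab in sorted(tree.leaf_ids)]
        self.leaf_labels = sorted(tree.leaf_ids)

    def loglike(self, codes: np.ndarray, r: np.ndarray) -> np.ndarray:
        """Vectorised log-likelihood.

        codes: (n_leaves, M) int array in leaf-label sorted order;
        r: (M,) rescaling factors.  Returns (M,) log-likelihoods
        (-inf where the likelihood is exactly zero).
        """
        tree, model = self.tree, self.model
        t = r[:, None] * tree.lengths[None, :]          # (M, nodes)
        ewt = np.exp(t[..., None] * model._eigvals)     # (M, nodes, 4)
        right, left = model._right, model._left
        leaf_row = {node: i for i, node in enumerate(self.leaf_order)}

        partial: Dict[int, np.ndarray] = {}
        for node in range(tree.n_nodes):
            if tree.is_leaf(node):
                continue
            acc = None
            for child in tree.children[node]:
                if tree.is_leaf(child):
                    x = left[:, codes[leaf_row[child]]].T   # (M, 4)
                else:
                    x = partial.pop(child) @ left.T
                y = np.einsum("mj,ij->mi", ewt[:, child, :] * x, right)
                np.maximum(y, 0.0, out=y)
                acc = y if acc is None else acc * y
            partial[node] = acc
        like = partial[tree.root] @ model.frequencies
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(like, 0.0))

    def fit(self, codes: np.ndarray, iters: int = 32,
            chunk: int = 20000) -> np.ndarray:
        """Golden-section ML estimate of r in [0, R_MAX] per column."""
        m_total = codes.shape[1]
        out = np.empty(m_total)
        for lo_i in range(0, m_total, chunk):
            sl = slice(lo_i, min(lo_i + chunk, m_total))
            out[sl] = self._fit_chunk(codes[:, sl], iters)
        return out

    def _fit_chunk(self, codes: np.ndarray, iters: int) -> np.ndarray:
        m = codes.shape[1]
        f = lambda x: self.loglike(codes, x)  # noqa: E731
        a = np.zeros(m)
        b = np.full(m, R_MAX)
        h = b - a
        c = b - _INVPHI * h
        d = a + _INVPHI * h
        fc = f(c)
        fd = f(d)
        for _ in range(iters):
            go_left = fc >= fd
            a = np.where(go_left, a, c)
            b = np.where(go_left, d, b)
            h = b - a
            c_n = np.where(go_left, b - _INVPHI * h, d)
            d_n = np.where(go_left, c, a + _INVPHI * h)
            x = np.where(go_left, c_n, d_n)
            fx = f(x)
            fc, fd = (np.where(go_left, fx, fd),
                      np.where(go_left, fc, fx))
            c, d = c_n, d_n
        r_hat = 0.5 * (a + b)
        f_mid = f(r_hat)
        f_lo = f(np.zeros(m))
        f_hi = f(np.full(m, R_MAX))
        r_hat = np.where(f_hi >= f_mid - 1e-12, R_MAX, r_hat)
        f_mid = np.maximum(f_mid, f_hi)
        r_hat = np.where(f_lo >= f_mid - 1e-12, 0.0, r_hat)
        return r_hat


def _columns_to_matrix(columns, species: Sequence[str]) -> np.ndarray:
    idx = {sp: i for i, sp in enumerate(species)}
    cols = list(columns)
    codes = np.full((len(species), len(cols)), GAP_CODE, dtype=np.int8)
    for j, col in enumerate(cols):
        bases = col.bases if isinstance(col, AlignmentColumn) else col
        for sp, sym in bases.items():
            if sp in idx:
                codes[idx[sp], j] = symbol_to_code(sym)
    return codes


def score_alignment(columns, tree: NeutralTree, model: SubstitutionModel,
                    iters: int = 32) -> ScoredTrack:
    """Score every reference position of an alignment.

    `columns` may be a reference-projected alignment (anything with
    ``species``, ``codes`` and optionally ``covered``/``chrom``/``start``
    attributes) or an iterable of :class:`AlignmentColumn` ordered by
    reference position.  Columns are scored independently, so the
    result does not depend on evaluation order or partitioning.
    """
    chrom, start = "chr1", 0
    if hasattr(columns, "codes") and hasattr(columns, "species"):
        species = list(columns.species)
        unknown = set(species) - set(tree.leaf_ids)
        if unknown:
            raise ValueError(
                f"alignment species not in tree: {sorted(unknown)}")
        codes = np.asarray(columns.codes, dtype=np.int8).copy()
        covered = getattr(columns, "covered", None)
        if covered is not None:
            codes[:, ~np.asarray(covered, dtype=bool)] = GAP_CODE
        chrom = getattr(columns, "chrom", chrom)
        start = getattr(columns, "start", start)
    else:
        cols = list(columns)
        species = sorted({sp for c in cols
                          for sp in (c.bases if isinstance(c, AlignmentColumn)
                                     else c)})
        unknown = set(species) - set(tree.leaf_ids)
        if unknown:
            raise ValueError(f"column species not in tree: {sorted(unknown)}")
        codes = _columns_to_matrix(cols, species)
        if cols and isinstance(cols[0], AlignmentColumn):
            start = cols[0].position

    n_pos = codes.shape[1]
    n_arr = np.zeros(n_pos)
    r_arr = np.zeros(n_pos)
    rs_arr = np.zeros(n_pos)
    scored = np.zeros(n_pos, dtype=bool)
    if n_pos == 0:
        return ScoredTrack(n_arr, r_arr, rs_arr, scored, chrom, start)

    present = codes != GAP_CODE                      # (S, N)
    # group columns by their gap pattern: one tree projection per pattern
    pat_view = np.ascontiguousarray(present.T).view(
        np.dtype((np.void, present.shape[0])))[:, 0]
    patterns, pat_inverse = np.unique(pat_view, return_inverse=True)

    kernels: Dict[frozenset, _TreeKernel] = {}
    for pat_id in range(len(patterns)):
        members = np.nonzero(pat_inverse == pat_id)[0]
        mask = present[:, members[0]]
        kept = [species[i] for i in np.nonzero(mask)[0]]
        if len(kept) < 3:
            continue  # unscored sentinel stays
        key = frozenset(kept)
        kern = kernels.get(key)
        if kern is None:
            proj = tree.project(kept)
            kern = _TreeKernel(proj, model)
            kernels[key] = kern
        sub = codes[np.ix_([species.index(lab) for lab in kern.leaf_labels],
                           members)]
        # de-duplicate identical columns within the pattern group
        col_view = np.ascontiguousarray(sub.T).view(
            np.dtype((np.void, sub.shape[0])))[:, 0]
        uniq, inv = np.unique(col_view, return_inverse=True)
        first = np.zeros(len(uniq), dtype=np.int64)
        first[inv[::-1]] = np.arange(len(inv))[::-1]
        r_uniq = kern.fit(sub[:, first], iters=iters)
        r_members = r_uniq[inv]
        n_arr[members] = kern.scope
        r_arr[members] = r_members
        rs_arr[members] = kern.scope * (1.0 - r_members)
        scored[members] = True

    return ScoredTrack(n_arr, r_arr, rs_arr, scored, chrom, start)


# ---------------------------------------------------------------------------
# coding-exon periodicity signal
# ---------------------------------------------------------------------------

def periodicity_bias(scores: Union[ScoredTrack, np.ndarray],
                     scored: Optional[np.ndarray] = None) -> float:
    """3-periodicity bias of a contiguous score slice.

    The maximum over the 3 reading-frame offsets of (mean RS at codon
    positions 1 and 2) minus (mean RS at codon position 3), with
    unscored positions excluded from the means.  Strong positive
    values are the signature of protein-coding constraint.
    """
    if isinstance(scores, ScoredTrack):
        rs = scores.rs
        mask = scores.scored
    else:
        rs = np.asarray(scores, dtype=float)
        mask = np.ones(len(rs), dtype=bool) if scored is None \
            else np.asarray(scored, dtype=bool)
    n = len(rs)
    if n < 3:
        raise ValueError("periodicity_bias needs a slice of length >= 3")
    phase = np.arange(n) % 3
    best = -np.inf
    for frame in range(3):
        codon_pos = (phase - frame) % 3          # 0,1 -> pos 1&2; 2 -> pos 3
        m12 = mask & (codon_pos != 2)
        m3 = mask & (codon_pos == 2)
        if not m12.any() or not m3.any():
            continue
        best = max(best, float(rs[m12].mean() - rs[m3].mean()))
    if best == -np.inf:
        raise ValueError("no scored positions to evaluate")
    return best
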