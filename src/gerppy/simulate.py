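"""Seeded simulation of alignments evolving on a rescaled neutral tree.

Columns are drawn i.i.d.: a root base from the stationary
frequencies, then evolution down each branch with the model's
transition probabilities at `r * branch_length`.  A per-column r
profile plants constrained blocks (r < 1), optionally with a
3-periodic codon pattern, in a neutral (r = 1) background.  Gaps are
injected independently per species and column; the real gap process
is autocorrelated, so this emulates alignment depth variation only in
aggregate.

The default test phylogeny is a 16-leaf balanced tree with total
branch length 5.8 substitutions per neutral site, mirroring the
phylogenetic scope of a deep mammalian alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .phylo_model import NeutralTree, SubstitutionModel
from .rate_scoring import GAP_CODE, AlignmentColumn
from .alignment_io import ReferenceProjectedAlignment

DEFAULT_SCOPE = 5.8
#: human-like base composition (~41% GC) to exercise unequal frequencies
DEFAULT_FREQUENCIES = (0.295, 0.205, 0.205, 0.295)

_BASES = "ACGT"


def balanced_tree(n_leaves: int = 16, scope: float = DEFAULT_SCOPE,
                  prefix: str = "sp") -> NeutralTree:
    """Balanced binary tree on `n_leaves` (a power of two) with equal
    branch lengths summing to `scope`."""
    if n_leaves < 2 or (n_leaves & (n_leaves - 1)) != 0:
        raise ValueError("n_leaves must be a power of two >= 2")
    n_edges = 2 * n_leaves - 2
    blen = scope / n_edges
    width = len(str(n_leaves))
    labels = [f"{prefix}{i + 1:0{width}d}" for i in range(n_leaves)]

    def build(lo: int, hi: int):
        if hi - lo == 1:
            return (labels[lo], blen)
        mid = (lo + hi) // 2
        return ([build(lo, mid), build(mid, hi)], blen)

    nested = ([build(0, n_leaves // 2), build(n_leaves // 2, n_leaves)], 0.0)
    return NeutralTree.from_nested(nested)


def default_tree() -> NeutralTree:
    """The 16-leaf, scope-5.8 test phylogeny."""
    return balanced_tree(16, DEFAULT_SCOPE)


def default_model() -> SubstitutionModel:
    """HKY85 with ts/tv ratio 2.0 and human-like base frequencies."""
    return SubstitutionModel(kappa=2.0, frequencies=DEFAULT_FREQUENCIES)


@dataclass
class SimulationSpec:
    """Everything needed to simulate one reference-projected alignment."""

    tree: NeutralTree = field(default_factory=default_tree)
    model: SubstitutionModel = field(default_factory=default_model)
    n_columns: int = 1000
    r_profile: Union[float, np.ndarray] = 1.0
    gap_rate: float = 0.02
    seed: int = 0
    reference: Optional[str] = None   # default: first leaf alphabetically
    chrom: str = "chr1"
    start: int = 0

    def profile_array(self) -> np.ndarray:
        prof = np.broadcast_to(np.asarray(self.r_profile, dtype=float),
                               (self.n_columns,)).copy()
        if np.any(prof < 0):
            raise ValueError("r profile values must be >= 0")
        return prof


def make_profile(n_columns: int, background: float = 1.0,
                 blocks: Sequence[Tuple[int, int, Union[float,
                                                        Sequence[float]]]] = ()
                 ) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    """Piecewise r profile with planted constrained blocks.

    Each block is ``(start, length, r)`` where r may be a scalar or a
    3-tuple of per-codon-position rates (cycled over the block for a
    3-periodic, exon-like pattern).  Returns the profile and the list
    of planted half-open intervals.
    """
    profile = np.full(n_columns, float(background))
    intervals: List[Tuple[int, int]] = []
    for start, length, r in blocks:
        if start < 0 or start + length > n_columns:
            raise ValueError("planted block outside the profile")
        r_arr = np.asarray(r, dtype=float)
        if r_arr.ndim == 0:
            profile[start:start + length] = float(r_arr)
        else:
            reps = -(-length // len(r_arr))
            profile[start:start + length] = np.tile(r_arr, reps)[:length]
        intervals.append((start, start + length))
    return profile, intervals


def _evolve(tree: NeutralTree, model: SubstitutionModel,
            profile: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample leaf states (n_leaves, n_columns) column-independently."""
    n = len(profile)
    states = np.empty((tree.n_nodes, n), dtype=np.int8)
    states[tree.root] = rng.choice(4, size=n, p=model.frequencies)

    # preorder traversal; group columns by r value so each unique rate
    # needs one transition matrix per branch
    uniq, inv = np.unique(profile, return_inverse=True)
    order = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in tree.children[node]:
            order.append(child)
            stack.append(child)

    for child in order:
        parent_states = states[_parent_of(tree, child)]
        child_states = np.empty(n, dtype=np.int8)
        for ui, r in enumerate(uniq):
            cols = np.nonzero(inv == ui)[0]
            if not len(cols):
                continue
            p = model.transition_matrix(r * tree.lengths[child])
            cum = np.cumsum(p, axis=1)
            u = rng.random(len(cols))
            child_states[cols] = (
                u[:, None] > cum[parent_states[cols]]).sum(axis=1)
        states[child] = child_states

    leaf_rows = [tree.leaf_ids[lab] for lab in sorted(tree.leaf_ids)]
    return states[leaf_rows]


def _parent_of(tree: NeutralTree, node: int) -> int:
    # trees are small; a linear scan cached on the tree is plenty
    cache = getattr(tree, "_parents", None)
    if cache is None:
        cache = {}
        for p in range(tree.n_nodes):
            for c in tree.children[p]:
                cache[c] = p
        object.__setattr__(tree, "_parents", cache)
    return cache[node]


def simulate_column(tree: NeutralTree, model: SubstitutionModel, r: float,
                    rng: Union[int, np.random.Generator] = 0
                    ) -> AlignmentColumn:
    """Draw a single alignment column evolving at rescaling `r`."""
    if r < 0:
        raise ValueError("r must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    leaves = _evolve(tree, model, np.array([float(r)]), rng)[:, 0]
    labels = sorted(tree.leaf_ids)
    return AlignmentColumn({lab: _BASES[leaves[i]]
                            for i, lab in enumerate(labels)})


def simulate_alignment(spec: SimulationSpec
                       ) -> Tuple[ReferenceProjectedAlignment, np.ndarray]:
    """Simulate a gap-injected, reference-projected alignment.

    Returns the alignment and the true per-column r profile.  The
    reference species is never gapped, so reference positions are
    simply 0..n_columns-1 (plus `start`).
    """
    profile = spec.profile_array()
    rng = np.random.default_rng(spec.seed)
    leaves = _evolve(spec.tree, spec.model, profile, rng)

    labels = sorted(spec.tree.leaf_ids)
    reference = spec.reference or labels[0]
    if reference not in spec.tree.leaf_ids:
        raise ValueError(f"reference {reference!r} not in tree")

    if not 0.0 <= spec.gap_rate < 1.0:
        raise ValueError("gap_rate must be in [0, 1)")
    if spec.gap_rate > 0:
        for i, lab in enumerate(labels):
            if lab == reference:
                continue
            gaps = rng.random(spec.n_columns) < spec.gap_rate
            leaves[i, gaps] = GAP_CODE

    # put the reference row first, as read_maf does
    order = [labels.index(reference)] + [i for i, lab in enumerate(labels)
                                         if lab != reference]
    species = [labels[i] for i in order]
    aln = ReferenceProjectedAlignment(
        reference=reference, species=species, codes=leaves[order],
        covered=np.ones(spec.n_columns, dtype=bool),
        chrom=spec.chrom, start=spec.start)
    return aln, profile


def write_truth(intervals: Sequence[Tuple[int, int]], profile: np.ndarray,
                bed_path, tsv_path, chrom: str = "chr1",
                start: int = 0) -> None:
    """Ground truth: planted intervals as BED, the r profile as TSV."""
    with open(bed_path, "w") as fh:
        for k, (s, e) in enumerate(intervals, start=1):
            fh.write(f"{chrom}\t{start + s}\t{start + e}\tplanted_{k}\n")
    with open(tsv_path, "w") as fh:
        fh.write("position\ttrue_r\n")
        for i, r in enumerate(profile):
            fh.write(f"{start + i}\t{r:.6g}\n")
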