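"""Neutral phylogenetic trees and the HKY85 substitution model.

The neutral tree carries branch lengths in expected substitutions per
neutral site; the total branch length ("phylogenetic scope") is the
per-site neutral rate when every species is present.  Columns with
missing species use the induced subtree on the ungapped leaves, with
degree-2 internal nodes collapsed so that the retained branch lengths
are preserved exactly.

The substitution process is the HKY85 continuous-time Markov model,
parameterised by a transition/transversion ratio kappa and stationary
base frequencies.  The rate matrix is normalised so that one unit of
branch length equals one expected substitution per site at
stationarity, which is what gives the neutral tree's branch-length
units their meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import dendropy

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: transition partners under HKY85 (purine<->purine, pyrimidine<->pyrimidine)
_TRANSITION = {(0, 2), (2, 0), (1, 3), (3, 1)}

_MIN_FREQ = 1e-6


class NewickParseError(ValueError):
    """Raised when a newick string cannot be turned into a NeutralTree."""


class SubstitutionModel:
    """HKY85 model with unit-rate normalisation.

    Parameters
    ----------
    kappa:
        Transition/transversion rate ratio (> 0).
    frequencies:
        Stationary probabilities of A, C, G, T.  Must be positive
        (minimum 1e-6) and sum to 1.
    """

    def __init__(self, kappa: float = 2.0,
                 frequencies: Sequence[float] = (0.25, 0.25, 0.25, 0.25)):
        kappa = float(kappa)
        if not np.isfinite(kappa) or kappa <= 0:
            raise ValueError(f"kappa must be positive, got {kappa}")
        freqs = np.asarray(frequencies, dtype=float)
        if freqs.shape != (4,):
            raise ValueError("frequencies must have length 4 (A, C, G, T)")
        if np.any(freqs < _MIN_FREQ):
            raise ValueError(
                f"stationary frequencies must all be >= {_MIN_FREQ}")
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ValueError("stationary frequencies must sum to 1")
        freqs = freqs / freqs.sum()

        self.kappa = kappa
        self.frequencies = freqs

        q = np.empty((4, 4))
        for a in range(4):
            for b in range(4):
                if a == b:
                    continue
                rate = freqs[b]
                if (a, b) in _TRANSITION:
                    rate *= kappa
                q[a, b] = rate
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise to one expected substitution per unit branch length
        mu = -(freqs * np.diag(q)).sum()
        q /= mu
        self._q = q

        # reversibility => D^1/2 Q D^-1/2 is symmetric; eigh is stable
        sq = np.sqrt(freqs)
        sym = (sq[:, None] * q) / sq[None, :]
        w, v = np.linalg.eigh(sym)
        self._eigvals = w
        self._right = v / sq[:, None]          # U  (columns are eigvecs of Q)
        self._left = v.T * sq[None, :]         # U^{-1}

    @property
    def rate_matrix(self) -> np.ndarray:
        """The normalised 4x4 instantaneous rate matrix Q."""
        return self._q.copy()

    def transition_matrix(self, t) -> np.ndarray:
        """P(t) = exp(Q t); `t` may be a scalar or an array.

        Returns an array of shape ``t.shape + (4, 4)`` whose rows are
        the conditional distributions p_ab(t).
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("branch length t must be non-negative")
        ewt = np.exp(t_arr[..., None] * self._eigvals)
        p = np.einsum("ij,...j,jk->...ik", self._right, ewt, self._left)
        p = np.maximum(p, 0.0)
        # t = 0 must be the exact identity (zero elapsed time)
        zero = t_arr == 0
        if np.any(zero):
            p[zero] = np.eye(4)
        return p

    def __repr__(self) -> str:  # pragma: no cover
        f = ", ".join(f"{x:.4f}" for x in self.frequencies)
        return f"SubstitutionModel(kappa={self.kappa}, frequencies=({f}))"


def transition_matrix(model: SubstitutionModel, t) -> np.ndarray:
    """Functional form of :meth:`SubstitutionModel.transition_matrix`."""
    return model.transition_matrix(t)


@dataclass(frozen=True)
class NeutralTree:
    """Rooted phylogeny stored in postorder arrays.

    ``children[i]`` lists the child node ids of node ``i``;
    ``lengths[i]`` is the branch length above node ``i`` (0 for the
    root); ``labels[i]`` is the species name for leaves and ``None``
    for internal nodes.  Node ids are postorder, so the root is the
    last node and every child precedes its parent.
    """

    children: tuple
    lengths: np.ndarray
    labels: tuple
    leaf_ids: dict = field(repr=False)

    @staticmethod
    def from_nested(nested) -> "NeutralTree":
        """Build from ``(label, length)`` leaves / ``(child_list, length)``
        internals, where the root's length is ignored."""
        children: list = []
        lengths: list = []
        labels: list = []

        def walk(node) -> int:
            payload, length = node
            if isinstance(payload, str):
                children.append(())
                labels.append(payload)
            else:
                kids = tuple(walk(c) for c in payload)
                children.append(kids)
                labels.append(None)
            lengths.append(0.0 if length is None else float(length))
            return len(children) - 1

        walk(nested)
        lengths[-1] = 0.0  # root carries no branch
        leaf_ids = {lab: i for i, lab in enumerate(labels) if lab is not None}
        arr = np.asarray(lengths, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("branch lengths must be finite and non-negative")
        return NeutralTree(tuple(children), arr, tuple(labels), leaf_ids)

    # -- basic structure ------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaves(self) -> tuple:
        return tuple(sorted(self.leaf_ids))

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    def scope(self) -> float:
        """Total branch length (neutral substitutions per site)."""
        return float(self.lengths.sum())

    def rescale(self, factor: float) -> "NeutralTree":
        """Return a copy with every branch multiplied by `factor`."""
        if factor < 0:
            raise ValueError("rescaling factor must be non-negative")
        return NeutralTree(self.children, self.lengths * factor,
                           self.labels, self.leaf_ids)

    # -- projection -----------------------------------------------------
    def project(self, present_species: Iterable[str]) -> Optional["NeutralTree"]:
        """Induced subtree on `present_species`, or None if < 3 remain.

        Degree-2 internal nodes are collapsed (their incident branch
        lengths summed) and the new root is the MRCA of the kept
        leaves, so the retained scope is exactly the sum of the edges
        of the induced subtree.
        """
        keep = set(present_species)
        unknown = keep - set(self.leaf_ids)
        if unknown:
            raise ValueError(f"species not in tree: {sorted(unknown)}")
        if len(keep) < 3:
            return None
        if len(keep) == self.n_leaves:
            return self

        def reduce(node: int, pending: float):
            """Return nested repr of the reduced subtree or None."""
            if self.is_leaf(node):
                if self.labels[node] in keep:
                    return (self.labels[node], pending)
                return None
            kids = []
            for c in self.children[node]:
                sub = reduce(c, float(self.lengths[c]))
                if sub is not None:
                    kids.append(sub)
            if not kids:
                return None
            if len(kids) == 1:
                # collapse degree-2 node: add this node's branch to child
                payload, length = kids[0]
                return (payload, length + pending)
            return (kids, pending)

        reduced = reduce(self.root, 0.0)
        # new root = MRCA of kept leaves: drop any pending root edge
        payload, _ = reduced
        return NeutralTree.from_nested((payload, 0.0))

    # -- serialisation --------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: int, with_len: bool) -> str:
            if self.is_leaf(node):
                s = self.labels[node]
            else:
                s = "(" + ",".join(
                    fmt(c, True) for c in self.children[node]) + ")"
            if with_len:
                s += f":{self.lengths[node]:.10g}"
            return s

        return fmt(self.root, False) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return (f"NeutralTree(n_leaves={self.n_leaves}, "
                f"scope={self.scope():.4f})")


def parse_newick(text: str) -> NeutralTree:
    """Parse a newick string into a :class:`NeutralTree`.

    Branch lengths are required on every non-root edge; missing
    lengths, duplicate leaf labels, and malformed syntax raise
    :class:`NewickParseError` naming the offending token.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise NewickParseError(f"malformed newick: {exc}") from exc

    seen: set = set()

    def convert(node, is_root: bool):
        length = node.edge.length
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label is None:
                raise NewickParseError("leaf without a label")
            if label in seen:
                raise NewickParseError(f"duplicate leaf label: {label!r}")
            seen.add(label)
            if length is None:
                raise NewickParseError(
                    f"missing branch length on leaf {label!r}")
            return (label, float(length))
        kids = [convert(c, False) for c in node.child_nodes()]
        if not is_root and length is None:
            raise NewickParseError(
                "missing branch length on an internal edge")
        return (kids, 0.0 if length is None else float(length))

    root = dtree.seed_node
    if root.is_leaf():
        raise NewickParseError("tree has a single leaf")
    nested = convert(root, True)
    tree = NeutralTree.from_nested(nested)
    if tree.scope() <= 0:
        raise NewickParseError("tree has zero total branch length")
    return tree


def read_newick(path) -> NeutralTree:
    """Read a newick file from disk."""
    with open(path) as fh:
        return parse_newick(fh.read())


def neutral_rate(tree: NeutralTree) -> float:
    """Sum of all branch lengths: the site's neutral substitution rate."""
    return tree.scope()


def project_tree(tree: NeutralTree,
                 present_species: Iterable[str]) -> Optional[NeutralTree]:
    """Induced subtree on `present_species`; None when fewer than 3 remain."""
    return tree.project(present_species)
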