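"""Phylogenetic likelihood machinery.

This module provides the shared core for conservation scanning and branch
acceleration testing: a rooted tree with addressable branches, reversible
nucleotide substitution models (JC69 / K80 / HKY85 / GTR), transition
probabilities ``P(t) = exp(Q t s)``, Felsenstein-pruning column likelihoods
with missing-data marginalization, and maximum-likelihood fitting of rate
scales (a global element scale ``s`` and an optional branch-specific
multiplier ``lam`` on a designated target branch).

Branch lengths are expected substitutions per site: every rate matrix is
normalized so that one unit of branch length equals one expected
substitution at stationarity, which makes the fitted scales directly
interpretable as rate multipliers.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
MISSING = 4  # internal code for '-', 'N', or an absent species

__all__ = [
    "PhyloTree",
    "SubstitutionModel",
    "ScaledModel",
    "FitResult",
    "parse_newick",
    "transition_matrix",
    "column_loglik",
    "tree_loglik",
    "encode_columns",
    "fit_scale",
]


class NewickError(ValueError):
    """Raised for malformed Newick input."""


class PhyloTree:
    """Rooted tree with branch lengths, flattened to arrays for fast pruning.

    Nodes are indexed in postorder (root last).  ``parent[i]`` is the parent
    index (-1 for the root) and ``length[i]`` the length of the branch above
    node ``i`` in expected substitutions/site.  A branch is addressed by the
    node below it, either through an explicit label or through the leaf set
    of its subtree (:meth:`find_branch`).
    """

    def __init__(self, parent, length, leaf_names, labels=None):
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(length, dtype=float)
        self.n_nodes = len(self.parent)
        self.leaf_names = list(leaf_names)
        self.n_leaves = len(self.leaf_names)
        self.labels = labels or {}
        if np.any(self.length[:-1] < 0):
            raise ValueError("negative branch length")
        if len(set(self.leaf_names)) != self.n_leaves:
            raise ValueError("leaf names are not unique")
        # children lists in postorder; leaves occupy indices 0..n_leaves-1
        self.children = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes - 1):
            self.children[self.parent[i]].append(i)
        self.root = self.n_nodes - 1
        self._leaf_sets = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"malformed Newick: {exc}") from exc
        dnodes = list(dtree.postorder_node_iter())
        for nd in dnodes[:-1]:
            if nd.edge.length is None:
                who = nd.taxon.label if nd.taxon else "an internal node"
                raise NewickError(f"missing branch length on the edge above {who}")
        # order: all leaves first (postorder among themselves), then internals
        leaves = [nd for nd in dnodes if nd.is_leaf()]
        internals = [nd for nd in dnodes if not nd.is_leaf()]
        order = leaves + internals
        index = {id(nd): i for i, nd in enumerate(order)}
        parent = np.full(len(order), -1, dtype=int)
        length = np.zeros(len(order))
        labels = {}
        for nd in order:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                length[i] = float(nd.edge.length)
            if not nd.is_leaf() and nd.label:
                labels[nd.label] = i
        leaf_names = [nd.taxon.label for nd in leaves]
        return cls(parent, length, leaf_names, labels)

    def to_newick(self) -> str:
        def rec(i):
            if i < self.n_leaves:
                core = self.leaf_names[i].replace(" ", "_")
            else:
                lab = next((k for k, v in self.labels.items() if v == i), "")
                core = "(" + ",".join(rec(c) for c in self.children[i]) + ")" + lab
            if i == self.root:
                return core
            return f"{core}:{self.length[i]:.10g}"

        return rec(self.root) + ";"

    # -- addressing ---------------------------------------------------

    def leaf_set(self, node: int) -> frozenset:
        """Leaf names of the subtree below ``node``."""
        if self._leaf_sets is None:
            sets = [None] * self.n_nodes
            for i in range(self.n_nodes):
                if i < self.n_leaves:
                    sets[i] = frozenset([self.leaf_names[i]])
                else:
                    s = frozenset()
                    for c in self.children[i]:
                        s |= sets[c]
                    sets[i] = s
            self._leaf_sets = sets
        return self._leaf_sets[node]

    def find_branch(self, spec) -> int:
        """Resolve a branch to its subtending node index.

        ``spec`` may be an explicit internal-node label, a single leaf name,
        or an iterable of leaf names naming the subtree below the branch.
        """
        if isinstance(spec, str):
            if spec in self.labels:
                return self.labels[spec]
            if spec in self.leaf_names:
                return self.leaf_names.index(spec)
            raise KeyError(f"no branch labelled {spec!r}")
        want = frozenset(spec)
        for i in range(self.n_nodes - 1):
            if self.leaf_set(i) == want:
                return i
        raise KeyError(f"no branch whose subtree has leaves {sorted(want)}")

    def subtree_nodes(self, node: int):
        """Indices of ``node`` and all its descendants."""
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.children[i])
        return out

    @property
    def total_length(self) -> float:
        return float(self.length[: self.root].sum())


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree` (lengths required)."""
    return PhyloTree.from_newick(text)


# ---------------------------------------------------------------------------
# substitution models


@dataclass
class SubstitutionModel:
    """Time-reversible nucleotide model in GTR parameterization.

    ``exchangeabilities`` are the six upper-triangle rates in the order
    AC, AG, AT, CG, CT, GT; the rate matrix is normalized to one expected
    substitution per unit branch length at stationarity.
    """

    family: str
    pi: np.ndarray
    exchangeabilities: np.ndarray
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.pi.shape != (4,) or np.any(self.pi < 0):
            raise ValueError("pi must be a nonnegative 4-vector")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities < 0):
            raise ValueError("need 6 nonnegative exchangeabilities")

    # -- canonical families -------------------------------------------

    @classmethod
    def jc69(cls):
        return cls("JC69", np.full(4, 0.25), np.ones(6))

    @classmethod
    def k80(cls, kappa: float = 2.0):
        # transitions AG and CT get kappa
        return cls("K80", np.full(4, 0.25), np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0]))

    @classmethod
    def hky85(cls, pi, kappa: float = 2.0):
        return cls("HKY85", pi, np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0]))

    @classmethod
    def gtr(cls, pi, rates):
        return cls("GTR", pi, rates)

    # -- rate matrix ---------------------------------------------------

    @property
    def Q(self) -> np.ndarray:
        r = self.exchangeabilities
        S = np.zeros((4, 4))
        S[0, 1] = S[1, 0] = r[0]
        S[0, 2] = S[2, 0] = r[1]
        S[0, 3] = S[3, 0] = r[2]
        S[1, 2] = S[2, 1] = r[3]
        S[1, 3] = S[3, 1] = r[4]
        S[2, 3] = S[3, 2] = r[5]
        Q = S * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(self.pi, np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        return Q / mu

    def _eigen(self):
        if self._eig is None:
            # symmetrize: B = D^1/2 Q D^-1/2 with D = diag(pi); pi>0 assumed
            d = np.sqrt(self.pi)
            B = (self.Q * d[:, None]) / d[None, :]
            w, V = np.linalg.eigh((B + B.T) / 2)
            self._eig = (w, V, d)
        return self._eig

    def transition_matrix(self, t: float, scale: float = 1.0) -> np.ndarray:
        """``P(t) = exp(Q t scale)``; rows sum to 1."""
        if t < 0 or scale < 0:
            raise ValueError("branch length and scale must be nonnegative")
        w, V, d = self._eigen()
        E = V * np.exp(w * t * scale)[None, :]
        P = (E @ V.T) * (d[None, :] / d[:, None])
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for an array of (already scaled) branch lengths."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be nonnegative")
        w, V, d = self._eigen()
        E = V[None, :, :] * np.exp(ts[:, None] * w[None, :])[:, None, :]
        P = np.einsum("kij,lj->kil", E, V) * (d[None, None, :] / d[None, :, None])
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=2, keepdims=True)

    # -- (de)serialization --------------------------------------------

    def to_text(self) -> str:
        lines = [
            f"family\t{self.family}",
            "pi\t" + "\t".join(f"{x:.10g}" for x in self.pi),
            "exchangeabilities\t" + "\t".join(f"{x:.10g}" for x in self.exchangeabilities),
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SubstitutionModel":
        fields = {}
        for line in _io.StringIO(text):
            if line.strip():
                key, *vals = line.rstrip("\n").split("\t")
                fields[key] = vals
        return cls(
            fields["family"][0],
            np.array([float(x) for x in fields["pi"]]),
            np.array([float(x) for x in fields["exchangeabilities"]]),
        )


@dataclass
class ScaledModel:
    """A substitution model with a global scale and optional branch multiplier.

    ``s`` rescales every branch; ``lam`` rescales the target branch on top of
    ``s``; ``lam = 1`` reduces to the global model.
    """

    model: SubstitutionModel
    s: float = 1.0
    lam: float = 1.0
    target: int | None = None  # node index below the target branch

    def __post_init__(self):
        if self.s < 0 or self.lam < 0:
            raise ValueError("scales must be nonnegative")


def transition_matrix(model: SubstitutionModel, t: float, scale: float = 1.0):
    return model.transition_matrix(t, scale)


# ---------------------------------------------------------------------------
# column likelihoods (Felsenstein pruning, vectorized over columns)


def encode_columns(column, leaf_names):
    """Encode per-species bases as an integer matrix (n_leaves, n_cols).

    ``column`` may be a dict mapping species -> base/str, or a 2-D character
    array aligned with ``leaf_names``.  Unknown characters raise; '-', 'N'
    and absent species become the missing code.
    """
    if isinstance(column, dict):
        unknown = set(column) - set(leaf_names)
        if unknown:
            raise ValueError(f"species not on the tree: {sorted(unknown)}")
        seqs = []
        width = max((len(v) for v in column.values()), default=1)
        for name in leaf_names:
            seqs.append(column.get(name, "-" * width))
        column = seqs
    out = np.full((len(leaf_names), len(column[0])), MISSING, dtype=np.int8)
    bad = set()
    for i, seq in enumerate(column):
        for j, ch in enumerate(str(seq).upper()):
            if ch in BASE_INDEX:
                out[i, j] = BASE_INDEX[ch]
            elif ch in "-N?.":
                out[i, j] = MISSING
            else:
                bad.add(ch)
    if bad:
        raise ValueError(f"unknown characters in alignment column: {sorted(bad)}")
    return out


def _branch_scales(tree: PhyloTree, s: float, lam: float, target):
    scales = np.full(tree.n_nodes, s, dtype=float)
    if target is not None and lam != 1.0:
        scales[target] *= lam
    return scales


def tree_loglik(
    tree: PhyloTree,
    model: SubstitutionModel,
    cols: np.ndarray,
    s: float = 1.0,
    lam: float = 1.0,
    target: int | None = None,
    per_column: bool = False,
):
    """Log-likelihood of encoded columns under the scaled model.

    ``cols`` is the (n_leaves, n_cols) int8 matrix from :func:`encode_columns`.
    Missing leaves are marginalized; partial likelihoods are rescaled per
    column to stay in range on deep trees.
    """
    if s < 0 or lam < 0:
        raise ValueError("scales must be nonnegative")
    cols = np.atleast_2d(np.asarray(cols, dtype=np.int8))
    if cols.shape[0] != tree.n_leaves:
        raise ValueError("column matrix does not match the tree's leaves")
    n_cols = cols.shape[1]
    scales = _branch_scales(tree, s, lam, target)
    P = model.transition_matrices(tree.length[: tree.root] * scales[: tree.root])

    leaf_like = np.ones((5, 4))
    leaf_like[:4] = np.eye(4)
    partial = [None] * tree.n_nodes
    logscale = np.zeros(n_cols)
    for i in range(tree.n_nodes):
        if i < tree.n_leaves:
            partial[i] = leaf_like[cols[i]]
        else:
            acc = np.ones((n_cols, 4))
            for c in tree.children[i]:
                acc *= partial[c] @ P[c].T
                partial[c] = None
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            acc /= mx[:, None]
            logscale += np.log(mx)
            partial[i] = acc
    site_ll = np.log(partial[tree.root] @ model.pi) + logscale
    return site_ll if per_column else float(site_ll.sum())


def column_loglik(tree: PhyloTree, scaled: ScaledModel, column) -> float:
    """Log-likelihood of a single alignment column.

    ``column`` maps species name to a one-character base ('A','C','G','T',
    '-' or 'N'); species absent from the mapping are treated as missing.
    """
    cols = encode_columns({k: v for k, v in column.items()}, tree.leaf_names)
    return float(
        tree_loglik(tree, scaled.model, cols, scaled.s, scaled.lam, scaled.target)
    )


# ---------------------------------------------------------------------------
# ML fitting of scales


@dataclass
class FitResult:
    s: float
    lam: float
    loglik: float
    converged: bool
    message: str = ""


SCALE_BOUNDS = (1e-4, 20.0)
LNL_TOL = 1e-6


def fit_scale(
    tree: PhyloTree,
    model: SubstitutionModel,
    cols: np.ndarray,
    free: str = "s",
    target: int | None = None,
    lam_lower: float = 1.0,
    bounds: tuple = SCALE_BOUNDS,
) -> FitResult:
    """Maximize the column log-likelihood over rate scales.

    ``free='s'`` fits the single global scale; ``free='s,lam'`` additionally
    fits the target-branch multiplier with ``lam >= lam_lower`` (the
    one-sided acceleration alternative).  Optimization is on log-scale
    parameters, bounded, with a deterministic start at 1.0.
    """
    cols = np.atleast_2d(np.asarray(cols, dtype=np.int8))
    if cols.shape[1] == 0:
        raise ValueError("need at least one alignment column")
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    if free == "s":
        res = minimize_scalar(
            lambda x: -tree_loglik(tree, model, cols, s=np.exp(x)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-7},
        )
        s = float(np.exp(res.x))
        return FitResult(s, 1.0, float(-res.fun), bool(res.success), res.message)

    if free != "s,lam":
        raise ValueError("free must be 's' or 's,lam'")
    if target is None:
        raise ValueError("target branch required to fit lam")
    llo = np.log(max(lam_lower, bounds[0]))

    def neg(x):
        return -tree_loglik(tree, model, cols, s=np.exp(x[0]), lam=np.exp(x[1]), target=target)

    bounds2 = [(lo, hi), (llo, hi)]
    x0 = np.array([0.0, max(llo, 0.0)])
    res = minimize(neg, x0=x0, method="L-BFGS-B", bounds=bounds2,
                   options={"ftol": 1e-12, "gtol": 1e-8})
    if not res.success:  # line-search failures near the boundary: polish
        res2 = minimize(neg, x0=res.x, method="Nelder-Mead", bounds=bounds2,
                        options={"xatol": 1e-8, "fatol": 1e-9})
        if res2.fun <= res.fun:
            res = res2
    s, lam = np.exp(res.x)
    return FitResult(float(s), float(lam), float(-res.fun), bool(res.success), str(res.message))
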