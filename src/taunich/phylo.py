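"""Fritz-Purvis phylogenetic dispersion D for binary niche membership.

Given a rooted bifurcating tree and a binary tip trait (membership in one
niche), internal node values are reconstructed by recursively averaging
daughter values, and the observed score ``d_obs`` is the sum of absolute
parent-child differences over every edge.  ``d_obs`` is scaled between the
expectation under random shuffles of the tip states (D = 1) and under a
Brownian threshold model at the same prevalence (D = 0):

    D = (d_obs - mean(d_brownian)) / (mean(d_random) - mean(d_brownian))

D below 0 indicates extreme clumping; p_random is the one-tailed probability
of a trait this clumped under random shuffling.  An effect size (Cohen's d)
compares D with the distribution of D recomputed for each random shuffle of
niche identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTrait",
    "DispersalResult",
    "TreeArrays",
    "sum_of_changes",
    "random_null",
    "brownian_null",
    "d_statistic",
    "PhyloDTest",
]


class NonBifurcatingError(ValueError):
    """Raised when a node has other than two children."""


@dataclass
class TreeArrays:
    """Flat array view of a rooted bifurcating tree for vectorised traversal.

    Nodes are indexed 0..n_nodes-1 with tips first (in tip-label order given
    by ``tip_labels``); ``postorder`` lists internal node indices children
    before parents; ``children`` holds each internal node's two child indices;
    ``parent`` is -1 at the root; ``edge_length`` is the branch above a node.
    """

    n_tips: int
    tip_labels: list[str]
    parent: np.ndarray
    children: np.ndarray  # internal-node rows x 2
    internal_postorder: np.ndarray  # internal node indices, postorder
    edge_length: np.ndarray

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeArrays":
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else str(id(lf)) for lf in leaves]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        order = np.argsort(labels, kind="stable")
        leaves = [leaves[i] for i in order]
        labels = [labels[i] for i in order]
        index: dict = {lf: i for i, lf in enumerate(leaves)}
        internals = []
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            kids = nd.child_nodes()
            if len(kids) != 2:
                raise NonBifurcatingError(
                    f"node {nd.taxon.label if nd.taxon else nd} has "
                    f"{len(kids)} children; a bifurcating tree is required"
                )
            index[nd] = len(labels) + len(internals)
            internals.append(nd)
        n = len(labels) + len(internals)
        parent = np.full(n, -1, dtype=np.int64)
        children = np.zeros((len(internals), 2), dtype=np.int64)
        edge_length = np.zeros(n)
        for nd in tree.preorder_node_iter():
            i = index[nd]
            edge_length[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.parent_node is not None:
                parent[i] = index[nd.parent_node]
        for j, nd in enumerate(internals):
            children[j] = [index[c] for c in nd.child_nodes()]
        return cls(
            n_tips=len(labels),
            tip_labels=labels,
            parent=parent,
            children=children,
            internal_postorder=np.array(
                [index[nd] for nd in internals], dtype=np.int64
            ),
            edge_length=edge_length,
        )


@dataclass
class PhyloTrait:
    """Rooted bifurcating tree plus a binary niche-membership trait."""

    tree: dendropy.Tree
    state_of_tip: dict[str, int]

    def __post_init__(self) -> None:
        self.arrays = TreeArrays.from_dendropy(self.tree)
        missing = set(self.arrays.tip_labels) - set(self.state_of_tip)
        if missing:
            raise ValueError(f"states missing for tips: {sorted(missing)[:5]} ...")
        states = np.array(
            [int(self.state_of_tip[t]) for t in self.arrays.tip_labels]
        )
        if not set(np.unique(states)) <= {0, 1}:
            raise ValueError("tip states must be 0/1")
        self.states = states
        self.prevalence = int(states.sum())
        if not 0 < self.prevalence < len(states):
            raise ValueError(
                "both trait states must be present (0 < prevalence < n_tips)"
            )


@dataclass
class DispersalResult:
    """Observed and null change scores with the scaled D statistic."""

    d_obs: float
    d_random: np.ndarray
    d_brownian: np.ndarray
    D: float
    p_random: float
    p_brownian: float
    cohens_d: float
    n_perm: int
    seed: int


def _changes(arr: TreeArrays, tip_states: np.ndarray) -> np.ndarray:
    """Sum of |parent - child| over edges, for each column of tip states.

    ``tip_states``: (n_tips,) or (n_tips, m).  Internal values by recursive
    daughter-averaging.
    """
    ts = np.atleast_2d(tip_states.T).T  # (n_tips, m)
    m = ts.shape[1]
    n_nodes = arr.parent.size
    vals = np.empty((n_nodes, m))
    vals[: arr.n_tips] = ts
    for i, node in enumerate(arr.internal_postorder):
        c0, c1 = arr.children[i]
        vals[node] = 0.5 * (vals[c0] + vals[c1])
    root = arr.internal_postorder[-1]
    nonroot = np.arange(n_nodes) != root
    diffs = np.abs(vals[arr.parent[nonroot]] - vals[nonroot])
    return diffs.sum(axis=0)


def sum_of_changes(pt: PhyloTrait) -> float:
    """Observed d: total absolute change in nodal trait values across edges."""
    return float(_changes(pt.arrays, pt.states.astype(float))[0])


def random_null(pt: PhyloTrait, n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """d scores for ``n_perm`` prevalence-conserving shuffles of tip states."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    base = pt.states.astype(float)
    shuffles = rng.permuted(
        np.tile(base, (n_perm, 1)), axis=1
    ).T  # (n_tips, n_perm)
    return _changes(pt.arrays, shuffles)


def _brownian_tip_values(
    arr: TreeArrays, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Unit-rate Brownian motion along the tree: (n_tips, n_perm) tip values."""
    if np.any(arr.edge_length[np.arange(arr.parent.size) != arr.internal_postorder[-1]] <= 0):
        raise ValueError("all (non-root) branch lengths must be > 0")
    n_nodes = arr.parent.size
    vals = np.zeros((n_nodes, n_perm))
    root = arr.internal_postorder[-1]
    preorder = [root]
    # children lookup by parent
    kids: dict[int, list[int]] = {}
    for i, node in enumerate(arr.internal_postorder):
        kids[node] = list(arr.children[i])
    stack = [root]
    while stack:
        node = stack.pop()
        for c in kids.get(node, []):
            vals[c] = vals[node] + np.sqrt(arr.edge_length[c]) * rng.standard_normal(
                n_perm
            )
            stack.append(c)
    return vals[: arr.n_tips]


def brownian_null(pt: PhyloTrait, n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """d scores under the Brownian threshold null at the observed prevalence.

    Each replicate evolves a unit-rate Brownian character along the tree and
    marks the ``prevalence`` tips with the largest values as state 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    tips = _brownian_tip_values(pt.arrays, n_perm, rng)  # (n_tips, n_perm)
    k = pt.prevalence
    thresh_idx = np.argpartition(tips, -k, axis=0)[-k:]
    states = np.zeros_like(tips)
    np.put_along_axis(states, thresh_idx, 1.0, axis=0)
    return _changes(pt.arrays, states)


def d_statistic(
    pt: PhyloTrait, n_perm: int = 1000, seed: int = 0
) -> DispersalResult:
    """The scaled dispersion statistic D with permutation p-values and effect size.

    p_random (one-tailed toward clustering) = (1 + #{d_random <= d_obs}) / (n_perm+1);
    p_brownian analogous against the Brownian ensemble.  Cohen's d compares D
    with D recomputed for each random shuffle (reusing the two null ensembles'
    means), signed so clustered traits give a positive effect size.
    """
    d_obs = sum_of_changes(pt)
    d_rand = random_null(pt, n_perm=n_perm, seed=seed)
    d_brown = brownian_null(pt, n_perm=n_perm, seed=seed + 1)
    mean_r, mean_b = float(d_rand.mean()), float(d_brown.mean())
    denom = mean_r - mean_b
    if abs(denom) < 1e-12:
        raise ZeroDivisionError(
            "random and Brownian null means coincide: D undefined on this tree"
        )
    D = (d_obs - mean_b) / denom
    p_random = float((1 + np.sum(d_rand <= d_obs)) / (n_perm + 1))
    p_brownian = float((1 + np.sum(d_brown <= d_obs)) / (n_perm + 1))
    D_null = (d_rand - mean_b) / denom
    sd_null = float(D_null.std(ddof=1)) if n_perm > 1 else np.nan
    cohens = float((D_null.mean() - D) / sd_null) if sd_null and sd_null > 0 else np.nan
    return DispersalResult(
        d_obs=d_obs,
        d_random=d_rand,
        d_brownian=d_brown,
        D=float(D),
        p_random=p_random,
        p_brownian=p_brownian,
        cohens_d=cohens,
        n_perm=n_perm,
        seed=seed,
    )


class PhyloDTest:
    """sklearn-style estimator for phylogenetic dispersion of a binary trait.

    ``fit(tree, states)`` takes a dendropy tree (or a path/newick string) and
    a mapping or Series tip -> {0,1}.  Fitted attributes: ``D_``, ``d_obs_``,
    ``p_random_``, ``p_brownian_``, ``cohens_d_``, ``result_``.
    """

    def __init__(self, n_perm: int = 1000, seed: int = 0):
        self.n_perm = n_perm
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_perm": self.n_perm, "seed": self.seed}

    def set_params(self, **params) -> "PhyloDTest":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        tree: dendropy.Tree | str,
        states: dict[str, int] | pd.Series,
    ) -> "PhyloDTest":
        if isinstance(tree, str):
            tree = dendropy.Tree.get(data=tree, schema="newick")
        if isinstance(states, pd.Series):
            states = states.to_dict()
        pt = PhyloTrait(tree=tree, state_of_tip={k: int(v) for k, v in states.items()})
        res = d_statistic(pt, n_perm=self.n_perm, seed=self.seed)
        self.result_ = res
        self.D_ = res.D
        self.d_obs_ = res.d_obs
        self.p_random_ = res.p_random
        self.p_brownian_ = res.p_brownian
        self.cohens_d_ = res.cohens_d
        return self
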