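"""Rarefaction, richness, Simpson evenness, Bray-Curtis dissimilarity and PCoA.

Univariate diversity follows the standard sequence-survey workflow: counts are
rarefied to a common depth (multivariate hypergeometric subsampling), richness
is the number of taxa observed, and evenness is inverse Simpson diversity
divided by richness.  Community dissimilarity uses Bray-Curtis, embedded by
classical principal coordinates analysis (Gower double-centering followed by
an eigendecomposition; negative eigenvalues are reported, not corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.special import gammaln

__all__ = [
    "RarefiedMatrix",
    "OrdinationResult",
    "rarefy",
    "expected_richness",
    "richness",
    "simpson_evenness",
    "bray_curtis",
    "pcoa",
    "PCoA",
    "diversity_table",
]


@dataclass
class RarefiedMatrix:
    """Counts subsampled to a common depth per chemostat."""

    counts: pd.DataFrame
    depth: int
    seed: int


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates for positive axes, all eigenvalues."""

    coordinates: pd.DataFrame  # samples x positive axes
    eigenvalues: np.ndarray  # all, descending
    variance_explained: np.ndarray  # per positive axis, relative to sum of positives


def rarefy(
    counts: pd.DataFrame, depth: int | None = None, seed: int = 0
) -> RarefiedMatrix:
    """Subsample each column without replacement to a common depth.

    ``depth=None`` uses the minimum column sum.  Deterministic given ``seed``.
    """
    mat = counts.to_numpy(dtype=np.int64)
    col_sums = mat.sum(axis=0)
    if depth is None:
        depth = int(col_sums.min())
    for j, total in enumerate(col_sums):
        if total < depth:
            raise ValueError(
                f"chemostat {counts.columns[j]!r} has only {total} reads, "
                f"cannot rarefy to {depth}"
            )
    rng = np.random.default_rng(seed)
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        if col_sums[j] == depth:
            out[:, j] = mat[:, j]
        else:
            out[:, j] = rng.multivariate_hypergeometric(mat[:, j], depth)
    return RarefiedMatrix(
        counts=pd.DataFrame(out, index=counts.index, columns=counts.columns),
        depth=depth,
        seed=seed,
    )


def expected_richness(column: np.ndarray, depth: int) -> float:
    """Analytic expected richness after rarefying one sample to ``depth``.

    E[S] = sum_j 1 - C(T - n_j, d) / C(T, d) under hypergeometric subsampling,
    evaluated with log-gamma for numerical safety.
    """
    n = np.asarray(column, dtype=np.int64)
    n = n[n > 0]
    total = n.sum()
    if depth > total:
        raise ValueError("depth exceeds sample total")

    def log_choose(a: np.ndarray, b: int) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    keep = (total - n) >= depth
    p_absent = np.zeros(len(n))
    p_absent[keep] = np.exp(
        log_choose(total - n[keep], depth) - log_choose(np.array(total), depth)
    )
    return float(np.sum(1.0 - p_absent))


def richness(column: pd.Series | np.ndarray) -> int:
    """Observed number of taxa with count > 0."""
    return int(np.count_nonzero(np.asarray(column) > 0))


def simpson_evenness(column: pd.Series | np.ndarray) -> tuple[float, int, float]:
    """Inverse Simpson diversity, richness, and Simpson evenness E = D^-1 / S."""
    n = np.asarray(column, dtype=float)
    total = n.sum()
    if total <= 0:
        raise ValueError("column sum must be > 0")
    p = n / total
    d = float(np.sum(p**2))
    inv_simpson = 1.0 / d
    s = richness(n)
    return inv_simpson, s, inv_simpson / s


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between chemostats (columns).

    BC(a, b) = sum |a_j - b_j| / sum (a_j + b_j); a pair of all-zero columns
    is defined as 0 with a warning.
    """
    x = matrix.to_numpy(dtype=float).T  # samples x taxa
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    n = x.shape[0]
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    zero_pair = den == 0
    if zero_pair.sum() > n:  # off-diagonal zero-sum pairs
        warnings.warn(
            "all-zero sample pair(s): Bray-Curtis defined as 0", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(zero_pair, 0.0, num / np.where(zero_pair, 1.0, den))
    np.fill_diagonal(bc, 0.0)
    return pd.DataFrame(bc, index=matrix.columns, columns=matrix.columns)


class PCoA:
    """Classical (metric) principal coordinates analysis.

    sklearn-style estimator: ``fit`` takes a square symmetric dissimilarity
    matrix with zero diagonal; fitted attributes are ``coordinates_``,
    ``eigenvalues_`` (all axes, descending) and ``variance_explained_``
    (per positive axis, relative to the sum of positive eigenvalues).
    Axis signs are fixed so the largest-magnitude loading on each axis is
    positive.  Negative eigenvalues are reported and logged, not corrected.

    Parameters
    ----------
    n_components:
        Number of positive axes to keep; ``None`` keeps all.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "PCoA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, dissimilarity: pd.DataFrame | np.ndarray) -> "PCoA":
        if isinstance(dissimilarity, pd.DataFrame):
            labels = list(dissimilarity.index)
            d = dissimilarity.to_numpy(dtype=float)
        else:
            d = np.asarray(dissimilarity, dtype=float)
            labels = [f"s{i}" for i in range(d.shape[0])]
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("dissimilarity must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("dissimilarity must have a zero diagonal")
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        evals, evecs = np.linalg.eigh((b + b.T) / 2)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        tol = max(abs(evals[0]), 1.0) * 1e-12
        pos = evals > tol
        if (evals < -tol).any():
            warnings.warn(
                f"{int((evals < -tol).sum())} negative eigenvalue(s) "
                "(non-Euclidean dissimilarity); reported uncorrected",
                stacklevel=2,
            )
        coords = evecs[:, pos] * np.sqrt(evals[pos])
        # deterministic sign: largest-|loading| entry positive per axis
        for k in range(coords.shape[1]):
            if coords.shape[0] and coords[np.argmax(np.abs(coords[:, k])), k] < 0:
                coords[:, k] *= -1
        if self.n_components is not None:
            coords = coords[:, : self.n_components]
        pos_sum = evals[pos].sum()
        var = evals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
        self.coordinates_ = pd.DataFrame(
            coords,
            index=labels,
            columns=[f"PCo{k + 1}" for k in range(coords.shape[1])],
        )
        self.eigenvalues_ = evals
        self.variance_explained_ = var
        return self

    def fit_transform(self, dissimilarity) -> pd.DataFrame:
        return self.fit(dissimilarity).coordinates_


def pcoa(dissimilarity: pd.DataFrame | np.ndarray) -> OrdinationResult:
    """Functional wrapper over :class:`PCoA`."""
    est = PCoA().fit(dissimilarity)
    return OrdinationResult(
        coordinates=est.coordinates_,
        eigenvalues=est.eigenvalues_,
        variance_explained=est.variance_explained_,
    )


def diversity_table(
    counts: pd.DataFrame,
    tau: pd.Series,
    depth: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-chemostat diversity summary on rarefied counts.

    Columns: tau_hours, depth, S (richness), inv_simpson, evenness.
    """
    rar = rarefy(counts, depth=depth, seed=seed)
    rows = []
    for chem in rar.counts.columns:
        col = rar.counts[chem]
        inv, s, e = simpson_evenness(col)
        rows.append(
            {
                "chemostat": chem,
                "tau_hours": float(tau[chem]),
                "depth": rar.depth,
                "S": s,
                "inv_simpson": inv,
                "evenness": e,
            }
        )
    return pd.DataFrame(rows).set_index("chemostat")
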