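"""Niche identification: correlation-distance k-means along the tau gradient.

Taxa whose relative-abundance patterns rise and fall together along the
residence-time gradient belong to the same niche.  Pairwise Pearson
correlations ``r`` of the gradient profiles give a distance ``d = 1 - r^2``;
k-means is run on the rows of that distance matrix (each taxon described by
its distances to every other taxon), the niche count is chosen at the elbow
of the within-cluster sum of squares, and each niche is summarised by the
combined relative abundance of its member taxa at each residence time.

Note the ``1 - r^2`` convention treats perfectly anticorrelated taxa as
distance 0; ``metric='1-r'`` is available for the signed alternative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .overlap import occupancy_filter, profile_matrix
from .simulate import CommunityMatrix

__all__ = [
    "CorrelationDistance",
    "NicheAssignment",
    "TrendFit",
    "correlation_distance",
    "kmeans_niches",
    "wss_curve",
    "elbow_select",
    "niche_profiles",
    "niche_trend",
    "NicheKMeans",
]

logger = logging.getLogger(__name__)


@dataclass
class CorrelationDistance:
    """Taxa-by-taxa distance matrix d = 1 - r^2 (or 1 - r)."""

    matrix: pd.DataFrame
    metric: str = "1-r2"
    dropped_taxa: list[str] = field(default_factory=list)


@dataclass
class NicheAssignment:
    """Cluster labels plus per-niche combined abundance profiles."""

    label_of_taxon: pd.Series  # taxon -> cluster id
    k: int
    wss_by_k: dict[int, float]
    niche_profile: pd.DataFrame  # niches x chemostats, combined rel. abundance
    niche_share: pd.Series  # niche -> mean combined relative abundance


@dataclass
class TrendFit:
    """Penalized-spline trend of a niche profile along log10 tau."""

    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    deviance_explained: float


def correlation_distance(
    profiles: pd.DataFrame | np.ndarray, metric: str = "1-r2"
) -> CorrelationDistance:
    """Pearson-correlation distance between taxon profiles (rows).

    Zero-variance profiles cannot carry a correlation and are removed first
    (logged).  ``metric`` is ``'1-r2'`` (default) or ``'1-r'``.
    """
    if metric not in {"1-r2", "1-r"}:
        raise ValueError("metric must be '1-r2' or '1-r'")
    if isinstance(profiles, pd.DataFrame):
        names = list(profiles.index)
        mat = profiles.to_numpy(dtype=float)
    else:
        mat = np.asarray(profiles, dtype=float)
        names = [f"t{i}" for i in range(mat.shape[0])]
    var = mat.var(axis=1)
    keep = var > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.warning("dropping %d zero-variance profile(s): %s", len(dropped), dropped)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 taxa with non-constant profiles")
    mat, names = mat[keep], [n for n, k in zip(names, keep) if k]
    r = np.corrcoef(mat)
    d = 1.0 - r if metric == "1-r" else 1.0 - r**2
    d = np.clip((d + d.T) / 2, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return CorrelationDistance(
        matrix=pd.DataFrame(d, index=names, columns=names),
        metric=metric,
        dropped_taxa=dropped,
    )


def kmeans_niches(
    dist: CorrelationDistance | pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 25,
) -> tuple[np.ndarray, float]:
    """k-means on the rows of the distance matrix; returns (labels, WSS).

    Mirrors the practice of handing a distance matrix straight to k-means:
    each taxon's feature vector is its distances to all taxa.  Best of
    ``n_init`` seeded restarts.
    """
    mat = dist.matrix if isinstance(dist, CorrelationDistance) else dist
    x = np.asarray(mat, dtype=float)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
    return km.labels_, float(km.inertia_)


def wss_curve(
    dist: CorrelationDistance | pd.DataFrame | np.ndarray,
    k_range: range | list[int] = range(1, 11),
    seed: int = 0,
    n_init: int = 25,
) -> dict[int, float]:
    """Within-cluster sum of squares for each candidate k."""
    mat = dist.matrix if isinstance(dist, CorrelationDistance) else dist
    n = np.asarray(mat).shape[0]
    out: dict[int, float] = {}
    for k in k_range:
        if k > n:
            break
        _, wss = kmeans_niches(dist, k, seed=seed, n_init=n_init)
        out[k] = wss
    return out


def elbow_select(wss_by_k: dict[int, float], weak_ratio: float = 0.1) -> int:
    """Knee of the WSS curve: the k maximising the second difference of log WSS.

    The knee is taken on the log scale so it responds to *relative* drops and
    is invariant to the overall scale of the curve.  Requires WSS at
    consecutive k.  When no knee stands out (max curvature below
    ``weak_ratio``) the argmax is still returned, with a "weak elbow"
    warning; the full curve should always be inspected alongside, as the
    choice of k is ultimately a judgement call.
    """
    ks = sorted(wss_by_k)
    if len(ks) < 3:
        raise ValueError("need WSS for at least 3 consecutive k values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("k values must be consecutive")
    wss = np.array([wss_by_k[k] for k in ks], dtype=float)
    if (wss < 0).any():
        raise ValueError("WSS values must be non-negative")
    floor = 1e-12 * max(wss.max(), 1.0)
    logw = np.log(np.maximum(wss, floor))
    second = logw[:-2] - 2 * logw[1:-1] + logw[2:]  # indexed by middle k
    best = int(ks[1 + int(np.argmax(second))])
    if second.max() < weak_ratio:
        warnings.warn(
            "weak elbow: no pronounced knee in the WSS curve; inspect wss_by_k",
            stacklevel=2,
        )
    return best


def niche_profiles(
    counts: pd.DataFrame,
    labels: pd.Series,
    wss_by_k: dict[int, float] | None = None,
) -> NicheAssignment:
    """Combined relative abundance of each niche at each residence time.

    For every chemostat the niche profile is the summed relative abundance
    (count / column total) of the niche's member taxa; ``niche_share`` is the
    mean of that combined relative abundance across chemostats.
    """
    col_tot = counts.sum(axis=0)
    rel = counts / col_tot
    member = rel.loc[labels.index]
    prof = member.groupby(labels).sum()
    prof.index.name = "niche"
    share = prof.mean(axis=1)
    share.name = "niche_share"
    k = int(labels.nunique())
    return NicheAssignment(
        label_of_taxon=labels,
        k=k,
        wss_by_k=wss_by_k or {},
        niche_profile=prof,
        niche_share=share,
    )


def niche_trend(
    profile: np.ndarray | pd.Series,
    tau: np.ndarray | pd.Series,
    df: int | None = None,
    alpha: float | None = None,
) -> TrendFit:
    """Penalized-spline smooth of a niche profile on log10 tau.

    Delegates to the statsmodels GAM facility (B-spline basis, penalty weight
    chosen by generalised cross-validation when ``alpha`` is not given).
    Returns fitted values, a 95% interval and the fraction of deviance
    explained.
    """
    from statsmodels.gam.api import BSplines, GLMGam

    y = np.asarray(profile, dtype=float)
    x = np.log10(np.asarray(tau, dtype=float))
    if y.size != x.size:
        raise ValueError("profile and tau must be aligned")
    if y.size < 8:
        raise ValueError("need at least 8 residence times for a trend fit")
    if np.allclose(y, y[0]):
        return TrendFit(
            fitted=np.full_like(y, y.mean()),
            ci_low=np.full_like(y, y.mean()),
            ci_high=np.full_like(y, y.mean()),
            deviance_explained=0.0,
        )
    if df is None:
        df = min(10, max(4, y.size // 4))
    basis = BSplines(x[:, None], df=[df], degree=[3])
    exog = np.ones((y.size, 1))
    if alpha is None:
        probe = GLMGam(y, exog=exog, smoother=basis, alpha=[1.0])
        probe.fit()  # select_penweight needs a fitted scale
        alpha = float(probe.select_penweight()[0][0])
    gam = GLMGam(y, exog=exog, smoother=basis, alpha=[alpha])
    res = gam.fit()
    pred = res.get_prediction(exog=exog, exog_smooth=x[:, None])
    ci = pred.conf_int()
    dev = 1.0 - res.deviance / res.null_deviance if res.null_deviance > 0 else 0.0
    return TrendFit(
        fitted=np.asarray(res.fittedvalues),
        ci_low=ci[:, 0],
        ci_high=ci[:, 1],
        deviance_explained=float(dev),
    )


class NicheKMeans:
    """Gradient-niche clustering, sklearn estimator style.

    ``fit`` takes a :class:`~taunich.simulate.CommunityMatrix` (or a counts
    DataFrame): taxa are occupancy-filtered, per-taxon profiles built, the
    ``1 - r^2`` distance computed, and k-means run either at a fixed ``k`` or
    at the elbow of the WSS curve (``k='auto'``).

    Parameters
    ----------
    k : int or 'auto'
    k_range : candidate k values scanned for the WSS curve
    cutoff : occupancy fraction (strictly-greater filter)
    metric : '1-r2' (default) or '1-r'
    embed : if True, k-means runs on a PCoA embedding of the distance matrix
        instead of its raw rows
    n_init, random_state : k-means restarts and seed

    Fitted attributes: ``labels_``, ``k_``, ``wss_by_k_``, ``distance_``,
    ``assignment_`` (a :class:`NicheAssignment`), ``kept_taxa_``.
    """

    def __init__(
        self,
        k: int | str = "auto",
        k_range: tuple[int, int] = (1, 10),
        cutoff: float = 0.70,
        metric: str = "1-r2",
        embed: bool = False,
        n_init: int = 25,
        random_state: int = 0,
    ):
        self.k = k
        self.k_range = k_range
        self.cutoff = cutoff
        self.metric = metric
        self.embed = embed
        self.n_init = n_init
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "k": self.k,
            "k_range": self.k_range,
            "cutoff": self.cutoff,
            "metric": self.metric,
            "embed": self.embed,
            "n_init": self.n_init,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "NicheKMeans":
        for key, v in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, v)
        return self

    def fit(self, X: CommunityMatrix | pd.DataFrame, y=None) -> "NicheKMeans":
        counts = X.counts if isinstance(X, CommunityMatrix) else X
        mask = occupancy_filter(counts, self.cutoff)
        kept = counts.loc[mask]
        profiles = pd.DataFrame(
            profile_matrix(kept.to_numpy(dtype=float)),
            index=kept.index,
            columns=kept.columns,
        )
        dist = correlation_distance(profiles, metric=self.metric)
        feats: pd.DataFrame | np.ndarray = dist.matrix
        if self.embed:
            from .diversity import PCoA

            feats = PCoA().fit_transform(dist.matrix).to_numpy()
        lo, hi = self.k_range
        wss = {}
        for kk in range(lo, min(hi, len(dist.matrix)) + 1):
            _, w = kmeans_niches(
                feats if not isinstance(feats, pd.DataFrame) else feats,
                kk,
                seed=self.random_state,
                n_init=self.n_init,
            )
            wss[kk] = w
        if self.k == "auto":
            k_use = elbow_select(wss)
        else:
            k_use = int(self.k)
        labels_arr, _ = kmeans_niches(
            feats, k_use, seed=self.random_state, n_init=self.n_init
        )
        labels = pd.Series(labels_arr, index=dist.matrix.index, name="niche")
        self.labels_ = labels
        self.k_ = k_use
        self.wss_by_k_ = wss
        self.distance_ = dist
        self.kept_taxa_ = list(dist.matrix.index)
        self.assignment_ = niche_profiles(counts, labels, wss_by_k=wss)
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        return self.fit(X).labels_
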