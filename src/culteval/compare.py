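"""Beta-diversity: transforms, Bray-Curtis, UPGMA clustering and non-metric MDS.

The pipeline order is fixed and matches common community-ecology practice:
variables (features) are standardized by their maximum across samples, then
fourth-root transformed, and only then pairwise Bray-Curtis similarities are
computed on the 0-100 scale (PRIMER convention).  Group-average (UPGMA)
agglomeration and Kruskal non-metric MDS with stress-1 operate on that
similarity matrix; a Pearson vector overlay relates original variables to
the ordination axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .profiles import TaxonProfile

logger = logging.getLogger("culteval")


# -- standardization / transformation ----------------------------------------


def standardize_transform(
    profile: TaxonProfile | np.ndarray,
    variable_standardize: str = "max",
    transform: str = "fourth_root",
) -> np.ndarray:
    """Feature-wise max standardization then elementwise fourth root.

    Accepts a TaxonProfile (features x samples) or a samples x features
    array; always returns a samples x features matrix ready for
    :func:`bray_curtis`.  All-zero features are left as zeros.
    """
    if isinstance(profile, TaxonProfile):
        X = profile.counts.T.astype(float)
    else:
        X = np.asarray(profile, dtype=float).copy()
    if (X < 0).any():
        raise ValueError("negative values")
    if variable_standardize == "max":
        maxima = X.max(axis=0)
        nz = maxima > 0
        X[:, nz] = X[:, nz] / maxima[nz]
    elif variable_standardize != "none":
        raise ValueError(f"unknown standardization {variable_standardize!r}")
    if transform == "fourth_root":
        X = X**0.25
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return X


# -- Bray-Curtis ---------------------------------------------------------------


@dataclass
class SimilarityMatrix:
    """Symmetric Bray-Curtis similarities on the 0-100 scale."""

    samples: list[str]
    values: np.ndarray
    transform: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")

    def to_dissimilarity(self) -> np.ndarray:
        return 100.0 - self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


def bray_curtis(
    X: np.ndarray, samples: list[str] | None = None
) -> SimilarityMatrix:
    """Pairwise Bray-Curtis similarity S = 100 * (1 - sum|x-y| / sum(x+y)).

    `X` is samples x features, non-negative.  A pair of all-zero samples has
    undefined similarity (NaN sentinel).
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("negative values")
    n = X.shape[0]
    samples = samples or [f"s{i}" for i in range(n)]
    sums = X.sum(axis=1)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            denom = sums[i] + sums[j]
            if denom == 0:
                out[i, j] = out[j, i] = np.nan
            else:
                num = np.abs(X[i] - X[j]).sum()
                out[i, j] = out[j, i] = 100.0 * (1.0 - num / denom)
    return SimilarityMatrix(samples=list(samples), values=out)


# -- UPGMA ---------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Group-average agglomeration recorded as (left, right, similarity, size).

    Node indexing follows the scipy convention: leaves are 0..n-1, the merge
    created at step k is node n+k.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float, int]]
    linkage_matrix: np.ndarray

    @property
    def merge_similarities(self) -> list[float]:
        return [m[2] for m in self.merges]


def upgma(sim: SimilarityMatrix) -> Dendrogram:
    """Unweighted group-average agglomerative clustering on similarities."""
    n = len(sim.samples)
    if n < 2:
        raise ValueError("clustering needs >= 2 samples")
    dissim = sim.to_dissimilarity()
    if np.isnan(dissim).any():
        raise ValueError("undefined similarities present")
    Z = linkage(squareform(dissim, checks=False), method="average")
    merges = [
        (int(a), int(b), 100.0 - float(h), int(size)) for a, b, h, size in Z
    ]
    return Dendrogram(leaves=list(sim.samples), merges=merges, linkage_matrix=Z)


def flat_clusters(dendro: Dendrogram, threshold_similarity: float = 60.0) -> dict[str, int]:
    """Cut the dendrogram at a similarity threshold; sample -> cluster label."""
    labels = fcluster(
        dendro.linkage_matrix, t=100.0 - threshold_similarity, criterion="distance"
    )
    return dict(zip(dendro.leaves, (int(l) for l in labels)))


def to_newick(dendro: Dendrogram) -> str:
    """Newick string with branch lengths on the dissimilarity (100-S) scale."""
    n = len(dendro.leaves)
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: dendro.leaves[i] for i in range(n)}
    for k, (a, b, s, _size) in enumerate(dendro.merges):
        h = (100.0 - s) / 2.0
        la, lb = h - height[a], h - height[b]
        node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + k] = h
    return node[n + len(dendro.merges) - 1] + ";"


# -- non-metric MDS ------------------------------------------------------------


@dataclass
class OrdinationResult:
    coordinates: np.ndarray           # samples x ndim
    stress: float                     # Kruskal stress-1
    n_restarts: int
    samples: list[str] = field(default_factory=list)
    stress_trace: list[float] = field(default_factory=list)
    axis_correlations: pd.DataFrame | None = None


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = (d**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _monotone_disparities(d: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Kruskal primary monotone regression of distances onto the
    dissimilarity order (ties free to be broken by the fit)."""
    dhat = np.empty_like(d)
    res = isotonic_regression(d[order])
    dhat[order] = res.x
    return dhat


def nmds(
    dissim: np.ndarray | SimilarityMatrix,
    ndim: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
    samples: list[str] | None = None,
) -> OrdinationResult:
    """Kruskal non-metric MDS minimizing stress-1.

    Each restart starts from a random configuration and alternates monotone
    regression of configuration distances onto the dissimilarity ranking
    (pool-adjacent-violators) with a Guttman majorization update.  The
    stress-1 trace within a restart is non-increasing: an iteration that
    fails to improve the best stress terminates the restart.  The best of
    `n_restarts` configurations is returned; fully deterministic under
    `seed`.
    """
    if isinstance(dissim, SimilarityMatrix):
        samples = samples or list(dissim.samples)
        D = dissim.to_dissimilarity()
    else:
        D = np.asarray(dissim, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("dissimilarities must be non-negative")
    n = D.shape[0]
    samples = samples or [f"s{i}" for i in range(n)]
    dvec = squareform(D, checks=False)
    # primary approach to ties: sort by dissimilarity, leaving tied blocks
    # free for the isotonic fit
    order = np.argsort(dvec, kind="stable")

    rng = np.random.default_rng(seed)
    best_X, best_stress, best_trace = None, np.inf, []
    for _ in range(max(1, n_restarts)):
        X = rng.normal(size=(n, ndim)) * (dvec.mean() if dvec.size else 1.0)
        prev = np.inf
        trace: list[float] = []
        for _it in range(max_iter):
            d = pdist(X)
            dhat = _monotone_disparities(d, order)
            stress = _stress1(d, dhat)
            if not np.isfinite(stress):
                break
            if stress >= prev - tol:
                # converged (or failed to improve): keep the trace monotone
                if stress < prev:
                    trace.append(stress)
                    prev = stress
                    last_X = X
                break
            trace.append(stress)
            prev = stress
            last_X = X
            # Guttman transform with unit weights
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = -squareform(ratio, checks=False)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = B @ X / n
        if trace and prev < best_stress:
            best_stress, best_X, best_trace = prev, last_X, trace
    if best_X is None:  # degenerate input (e.g. all-zero dissimilarities)
        best_X = np.zeros((n, ndim))
        best_stress, best_trace = 0.0, [0.0]
    return OrdinationResult(
        coordinates=best_X - best_X.mean(axis=0),
        stress=best_stress,
        n_restarts=n_restarts,
        samples=samples,
        stress_trace=best_trace,
    )


def vector_overlay(
    ordination: OrdinationResult,
    variables: pd.DataFrame | np.ndarray,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Pearson correlation of each variable with the ordination axes.

    `variables` is samples x variables (rows aligned with the ordination).
    Returns one row per variable with r against each axis, plus the vector
    length sqrt(sum r^2) times `scale`.  Constant variables get zero-length
    vectors with a warning.
    """
    if isinstance(variables, pd.DataFrame):
        names = [str(c) for c in variables.columns]
        V = variables.to_numpy(dtype=float)
    else:
        V = np.asarray(variables, dtype=float)
        names = [f"v{i}" for i in range(V.shape[1])]
    X = ordination.coordinates
    if V.shape[0] != X.shape[0]:
        raise ValueError("variables rows must align with ordination samples")
    rows = []
    for j, name in enumerate(names):
        v = V[:, j]
        if np.ptp(v) == 0:
            logger.warning("variable %s is constant; zero-length vector", name)
            rs = [0.0] * X.shape[1]
        else:
            rs = [float(np.corrcoef(v, X[:, k])[0, 1]) for k in range(X.shape[1])]
        length = scale * float(np.sqrt(np.sum(np.square(rs))))
        rows.append([name, *rs, length])
    cols = ["variable"] + [f"r_axis{k + 1}" for k in range(X.shape[1])] + ["length"]
    df = pd.DataFrame(rows, columns=cols).set_index("variable")
    ordination.axis_correlations = df
    return df
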