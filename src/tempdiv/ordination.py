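"""Temporal beta diversity: Bray-Curtis -> NMDS -> per-plot dispersion.

The beta-diversity measure used throughout the package is multivariate
dispersion: all of a year's temporal samples (across every plot) are
ordinated jointly by non-metric multidimensional scaling of their
pairwise Bray-Curtis dissimilarities, and each plot's score is the mean
Euclidean distance between the plot's centroid and its constituent
samples in the ordination space. Because dispersion is computed from the
full dissimilarity structure rather than from alpha/gamma differences,
it is mathematically independent of the other diversity components.

NMDS here is Kruskal's: minimise stress-1
``sqrt(sum (d_ij - dhat_ij)^2 / sum d_ij^2)`` over configurations, with
``dhat`` the least-squares monotone (isotonic) regression of the
configuration distances on the rank order of the dissimilarities. The
solver starts from classical scaling (PCoA) plus random restarts and
uses safeguarded Guttman-transform steps, so the accepted stress never
increases within a run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _sp_braycurtis
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "NmdsConfig",
    "OrdinationResult",
    "DispersionResult",
    "bray_curtis",
    "dissimilarity_matrix",
    "pcoa",
    "isotonic_fit",
    "nmds",
    "dispersion_scores",
]


@dataclass
class NmdsConfig:
    """NMDS solver settings (dimensionality, restarts, convergence)."""

    k: int = 2
    n_restarts: int = 20
    max_iter: int = 300
    tol: float = 1e-7
    seed: int = 0
    standardize: str = "none"  # {"none", "wisconsin", "sqrt"}
    engine: str = "nmds"  # {"nmds", "pcoa"}


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k, centered
    stress: float
    k: int
    converged: bool
    restarts_run: int
    stress_init: float = float("nan")  # stress at the PCoA start

    def coords_array(self) -> np.ndarray:
        return self.coordinates.to_numpy()


@dataclass
class DispersionResult:
    """Per-plot distance-to-centroid scores in ordination space."""

    scores: pd.DataFrame  # plot_id, treatment?, dispersion, samples_per_plot
    centroids: pd.DataFrame  # plot_id x k
    excluded: list = field(default_factory=list)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_sp_braycurtis(x, y))


def _standardize(values: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return values
    if how == "sqrt":
        return np.sqrt(values)
    if how == "wisconsin":
        v = values / values.max(axis=0, keepdims=True)
        return v / v.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown standardization {how!r}")


def dissimilarity_matrix(matrix, standardize: str = "none") -> pd.DataFrame:
    """All-pairs Bray-Curtis matrix for the rows of an abundance matrix.

    Accepts an :class:`~tempdiv.data_model.AbundanceMatrix` or a labelled
    count DataFrame. One matrix per year across all plots jointly is the
    intended use: the resulting ordination places every temporal sample
    of every plot in a common space.
    """
    counts = matrix.counts if hasattr(matrix, "counts") else matrix
    values = np.asarray(counts, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples for an ordination input")
    zero = values.sum(axis=1) == 0
    if zero.any():
        bad = list(np.asarray(counts.index)[zero][:5])
        raise ValueError(f"all-zero sample row(s): {bad}")
    values = _standardize(values, standardize)
    d = squareform(pdist(values, metric="braycurtis"))
    return pd.DataFrame(d, index=counts.index, columns=counts.index)


def _validate_d(D) -> np.ndarray:
    d = np.asarray(D, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.abs(np.diag(d)).max() > 1e-12:
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return d


def pcoa(D, k: int = 2) -> np.ndarray:
    """Classical (metric) scaling of a dissimilarity matrix.

    Eigen-decomposes the double-centered matrix ``-J D^2 J / 2`` and
    returns the top-k positive-eigenvalue axes scaled by sqrt(eigenvalue).
    Used as the deterministic NMDS start and as the alternative
    dispersion engine.
    """
    d = _validate_d(D)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10, 1e-10 * abs(evals[0]))
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no positive eigenvalues; degenerate dissimilarity matrix")
    if k > n_pos:
        warnings.warn(
            f"requested k={k} but only {n_pos} positive eigenvalue(s); reducing k",
            stacklevel=2,
        )
        k = n_pos
    return evecs[:, :k] * np.sqrt(evals[:k])


def isotonic_fit(values, tie_groups=None, weights=None) -> np.ndarray:
    """Least-squares monotone non-decreasing fit (pool-adjacent-violators).

    `values` must already be ordered by the rank of the dissimilarities.
    With `tie_groups` (one group label per value, contiguous), Kruskal's
    primary approach to ties is applied: values within a tie group are
    free to order themselves, implemented by sorting each group ascending
    before pooling and undoing the permutation afterwards.
    """
    y = np.asarray(values, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if y.shape != w.shape:
        raise ValueError("weights must align with values")

    perm = np.arange(len(y))
    if tie_groups is not None:
        g = np.asarray(tie_groups)
        if g.shape != y.shape:
            raise ValueError("tie_groups must align with values")
        # stable sort by (group, value): within a tie group the fit is
        # unconstrained, which for least squares means fitting the sorted values
        perm = np.lexsort((y, g))
        y, w = y[perm], w[perm]

    # pool-adjacent-violators with weighted means
    means = list(y[:1])
    wts = list(w[:1])
    sizes = [1]
    for i in range(1, len(y)):
        means.append(y[i]); wts.append(w[i]); sizes.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, s2 = means.pop(), wts.pop(), sizes.pop()
            m1, w1, s1 = means.pop(), wts.pop(), sizes.pop()
            wsum = w1 + w2
            means.append((m1 * w1 + m2 * w2) / wsum)
            wts.append(wsum)
            sizes.append(s1 + s2)
    fitted = np.repeat(means, sizes)
    out = np.empty_like(fitted)
    out[perm] = fitted
    return out


def _stress_and_dhat(dist: np.ndarray, order: np.ndarray, groups: np.ndarray):
    """Kruskal stress-1 and the isotonic targets for one configuration."""
    fitted = isotonic_fit(dist[order], tie_groups=groups)
    dhat = np.empty_like(dist)
    dhat[order] = fitted
    denom = float((dist**2).sum())
    if denom == 0:
        return np.inf, dhat
    stress = float(np.sqrt(((dist - dhat) ** 2).sum() / denom))
    return stress, dhat


def _guttman(x: np.ndarray, dhat_sq: np.ndarray, dist_sq: np.ndarray) -> np.ndarray:
    """One Guttman-transform update toward the current isotonic targets."""
    n = x.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dist_sq > 0, dhat_sq / dist_sq, 0.0)
    b = -ratio
    np.fill_diagonal(b, 0.0)
    np.fill_diagonal(b, -b.sum(axis=1))
    return (b @ x) / n


def _minimize_stress(d: np.ndarray, x0: np.ndarray, order: np.ndarray,
                     groups: np.ndarray, max_iter: int, tol: float):
    """Safeguarded stress-1 descent from one starting configuration.

    Stress-1 is invariant to a global rescaling of the configuration,
    so the iteration is free to drift toward zero scale; every accepted
    step therefore renormalises the configuration so its RMS distance
    matches the RMS input dissimilarity, keeping output distances on
    the input scale.
    """
    iu = np.triu_indices(d.shape[0], k=1)
    target_rms = float(np.sqrt((d[iu] ** 2).mean()))

    def _renorm(x, dist):
        rms = float(np.sqrt((dist[iu] ** 2).mean()))
        if rms > 0:
            c = target_rms / rms
            return x * c, dist * c, c
        return x, dist, 1.0

    x = x0.copy()
    dist_sq = squareform(pdist(x))
    x, dist_sq, _ = _renorm(x, dist_sq)
    stress, dhat = _stress_and_dhat(dist_sq[iu], order, groups)
    converged = False
    for _ in range(max_iter):
        dhat_sq = np.zeros_like(dist_sq)
        dhat_sq[iu] = dhat
        dhat_sq += dhat_sq.T
        x_prop = _guttman(x, dhat_sq, dist_sq)
        # accept only stress-decreasing steps; back off toward x otherwise
        step = 1.0
        for _ls in range(12):
            x_new = x + step * (x_prop - x)
            dist_new = squareform(pdist(x_new))
            s_new, dhat_new = _stress_and_dhat(dist_new[iu], order, groups)
            if s_new <= stress:
                break
            step *= 0.5
        else:
            converged = True
            break
        x_new, dist_new, c = _renorm(x_new, dist_new)
        dhat_new = dhat_new * c  # isotonic fit scales linearly with its input
        if stress - s_new < tol * max(stress, 1e-12):
            x, dist_sq, stress, dhat = x_new, dist_new, s_new, dhat_new
            converged = True
            break
        x, dist_sq, stress, dhat = x_new, dist_new, s_new, dhat_new
    return x, stress, converged


def nmds(D, k: int = 2, n_restarts: int = 20, max_iter: int = 300,
         tol: float = 1e-7, seed: int = 0) -> OrdinationResult:
    """Non-metric multidimensional scaling by Kruskal stress-1 minimisation.

    The first start is the deterministic PCoA configuration; the
    remaining ``n_restarts - 1`` starts are random Gaussian
    configurations. The best (lowest-stress) solution is returned,
    centered and rotated to its principal axes. Equal dissimilarities
    are tied under Kruskal's primary approach. A stress above 0.20 —
    conventionally considered an unreliable configuration — triggers a
    warning.
    """
    labels = D.index if isinstance(D, pd.DataFrame) else None
    d = _validate_d(D)
    n = d.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    iu = np.triu_indices(n, k=1)
    dvec = d[iu]
    order = np.argsort(dvec, kind="stable")
    # tie groups: equal dissimilarities form one group each
    groups = np.searchsorted(np.unique(dvec), dvec[order])

    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k-reduction warning handled below
        x0 = pcoa(d, k)
    if x0.shape[1] < k:
        x0 = np.hstack([x0, np.zeros((n, k - x0.shape[1]))])

    best = None
    stress_init = np.nan
    restarts_run = 0
    for r in range(max(1, n_restarts)):
        start = x0 if r == 0 else rng.standard_normal((n, k)) * np.std(dvec)
        x, stress, conv = _minimize_stress(d, start, order, groups, max_iter, tol)
        restarts_run += 1
        if r == 0:
            stress_init = stress
        if best is None or stress < best[1]:
            best = (x, stress, conv)
    x, stress, conv = best
    if not conv:
        warnings.warn("NMDS did not converge in any restart; returning best found",
                      stacklevel=2)
    if stress > 0.20:
        warnings.warn(f"NMDS stress {stress:.3f} > 0.20; ordination may be unreliable",
                      stacklevel=2)

    x = x - x.mean(axis=0)
    # rotate to principal axes for a deterministic, reportable orientation
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    # sign convention: largest-magnitude loading positive on each axis
    for j in range(x.shape[1]):
        i = np.argmax(np.abs(x[:, j]))
        if x[i, j] < 0:
            x[:, j] = -x[:, j]
    coords = pd.DataFrame(x, index=labels if labels is not None else range(n),
                          columns=[f"NMDS{i+1}" for i in range(x.shape[1])])
    return OrdinationResult(coordinates=coords, stress=stress, k=x.shape[1],
                            converged=conv, restarts_run=restarts_run,
                            stress_init=stress_init)


def dispersion_scores(coordinates, plot_assignment) -> DispersionResult:
    """Mean distance from each plot's centroid to its samples.

    Parameters
    ----------
    coordinates
        Sample coordinates (``OrdinationResult``, DataFrame or array).
    plot_assignment
        Plot id per sample row (sequence or Series aligned with rows).

    Plots with a single sample have no meaningful dispersion; they are
    reported in ``excluded`` with a missing score rather than dropped
    silently. Scores are invariant under rigid motions (rotation,
    reflection, translation) of the coordinates.
    """
    if isinstance(coordinates, OrdinationResult):
        coordinates = coordinates.coordinates
    x = np.asarray(coordinates, dtype=float)
    plots = np.asarray(plot_assignment)
    if len(plots) != x.shape[0]:
        raise ValueError("plot_assignment must align with coordinate rows")

    rows, cents, excluded = [], {}, []
    for plot in pd.unique(plots):
        xi = x[plots == plot]
        centroid = xi.mean(axis=0)
        cents[plot] = centroid
        if xi.shape[0] < 2:
            excluded.append(plot)
            score = np.nan
        else:
            score = float(np.linalg.norm(xi - centroid, axis=1).mean())
        rows.append({"plot_id": plot, "dispersion": score,
                     "samples_per_plot": int(xi.shape[0])})
    scores = pd.DataFrame(rows)
    centroids = pd.DataFrame.from_dict(cents, orient="index",
                                       columns=[f"axis{i+1}" for i in range(x.shape[1])])
    centroids.index.name = "plot_id"
    return DispersionResult(scores=scores, centroids=centroids, excluded=excluded)
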