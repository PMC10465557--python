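"""Spatially corrected statistics for gridded diversity summaries.

Spatial autocorrelation inflates the nominal sample size of correlation
tests between mapped variables.  The modified t-test of spatial
association (Dutilleul 1993) replaces the sample size n in the Pearson
test with an estimated effective sample size M computed from
distance-class autocovariance estimates of both variables:

    M = 1 + tr(B Sx) tr(B Sy) / tr(B Sx B Sy)

with B = I - J/n the centering matrix and Sx, Sy the estimated spatial
covariance matrices of x and y.  The test statistic
F = (M - 2) r^2 / (1 - r^2) is referred to F(1, M - 2) with fractional
degrees of freedom.  For spatially independent data M ~= n and the
classical Pearson test is recovered.

Moran's I with a permutation null is provided for residual
autocorrelation checks (one-sided, greater), plus plain Pearson
sampling-artifact screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModifiedTTestResult:
    """Spatially corrected correlation test result."""

    r: float
    F: float
    dof: float  # effective degrees of freedom M - 2, fractional
    p: float
    n: int
    effective_n: float


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float  # -1/(n-1) under the null
    p: float
    n_permutations: int


def _class_covariance_matrix(z: np.ndarray, class_idx: np.ndarray, n_classes: int) -> np.ndarray:
    """Estimated spatial covariance matrix from distance-class averages.

    Off-diagonal entries of pairs in distance class k share the average
    cross-product of centered values over that class; the diagonal is the
    (population) variance.
    """
    n = z.size
    zc = z - z.mean()
    prod = np.outer(zc, zc)
    iu = np.triu_indices(n, k=1)
    pair_prod = prod[iu]
    cov = np.zeros(n_classes)
    for k in range(n_classes):
        sel = class_idx == k
        if sel.any():
            cov[k] = pair_prod[sel].mean()
    sigma = np.zeros((n, n))
    sigma[iu] = cov[class_idx]
    sigma = sigma + sigma.T
    np.fill_diagonal(sigma, (zc**2).mean())
    return sigma


def modified_ttest(x, y, coords, n_classes: int = 13) -> ModifiedTTestResult:
    """Dutilleul's modified t-test of association between two mapped variables.

    ``coords`` are point locations in projected meters (n x 2).  Distance
    classes are equal-count (quantile) classes of the pairwise distances,
    13 by default; with fewer points than classes the class count is
    reduced with a warning.  Raises for constant input or n < 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("modified t-test needs at least 10 points")
    if y.size != n or coords.shape[0] != n:
        raise ValueError("x, y and coords must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable in modified t-test")
    n_pairs = n * (n - 1) // 2
    if n_classes > n_pairs:
        logger.warning("reducing distance classes from %d to %d", n_classes, n_pairs)
        n_classes = n_pairs

    d = pdist(coords)
    # equal-count class breaks on the pairwise distance distribution
    qs = np.quantile(d, np.linspace(0, 1, n_classes + 1)[1:-1])
    class_idx = np.searchsorted(qs, d, side="left")

    sx = _class_covariance_matrix(x, class_idx, n_classes)
    sy = _class_covariance_matrix(y, class_idx, n_classes)
    b = np.eye(n) - np.full((n, n), 1.0 / n)
    bsx = b @ sx
    bsy = b @ sy
    denom = np.trace(bsx @ bsy)
    if not np.isfinite(denom) or denom <= 0:
        m_hat = float(n)  # degenerate estimate; fall back to no correction
    else:
        m_hat = 1.0 + np.trace(bsx) * np.trace(bsy) / denom
    m_hat = float(np.clip(m_hat, 2.0 + 1e-9, n))

    r = float(np.corrcoef(x, y)[0, 1])
    dof = m_hat - 2.0
    f_stat = dof * r**2 / max(1.0 - r**2, 1e-300)
    p = float(stats.f.sf(f_stat, 1, dof))
    return ModifiedTTestResult(r=r, F=float(f_stat), dof=dof, p=p, n=n, effective_n=m_hat)


def quadratic_latitude_test(
    values, centroid_lat, coords, n_classes: int = 13
) -> dict[str, ModifiedTTestResult]:
    """Modified t-tests of a response against latitude, linear and quadratic.

    The linear term uses absolute latitude, the quadratic squared latitude.
    A response humped in the subtropics and symmetric about the equator
    yields a negative quadratic correlation.
    """
    lat = np.asarray(centroid_lat, dtype=float)
    return {
        "linear": modified_ttest(values, np.abs(lat), coords, n_classes=n_classes),
        "quadratic": modified_ttest(values, lat**2, coords, n_classes=n_classes),
    }


def knn_weights(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """Row-standardized k-nearest-neighbour weight matrix."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of locations")
    dm = squareform(pdist(coords))
    np.fill_diagonal(dm, np.inf)
    w = np.zeros((n, n))
    nn = np.argsort(dm, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    w[rows, nn.ravel()] = 1.0
    return w / w.sum(axis=1, keepdims=True)


def inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    """Row-standardized inverse-distance weight matrix."""
    dm = squareform(pdist(np.asarray(coords, dtype=float)))
    with np.errstate(divide="ignore"):
        w = 1.0 / dm
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def morans_i(
    values,
    coords=None,
    weights="knn",
    k: int = 8,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> MoranResult:
    """Moran's I with a one-sided (greater) permutation test.

    ``weights`` is either "knn" (row-standardized k-nearest, default),
    "idw" (row-standardized inverse distance), or a precomputed (n, n)
    weight matrix (e.g. rook adjacency on a lattice).  The permutation
    p-value is (1 + #{I_perm >= I_obs}) / (n_perm + 1).
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 10:
        raise ValueError("Moran's I needs at least 10 locations")
    if np.ptp(z) == 0:
        raise ValueError("constant values in Moran's I")
    if isinstance(weights, str):
        if coords is None:
            raise ValueError("coords required when weights is a scheme name")
        if weights == "knn":
            w = knn_weights(coords, k=k)
        elif weights == "idw":
            w = inverse_distance_weights(coords)
        else:
            raise ValueError(f"unknown weight scheme {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape mismatch")

    zc = z - z.mean()
    s0 = w.sum()
    denom = (zc**2).sum()
    i_obs = n / s0 * (zc @ w @ zc) / denom

    rng = np.random.default_rng(seed)
    # vectorized permutations: quadratic form over the nonzero weight pairs
    ii, jj = np.nonzero(w)
    ww = w[ii, jj]
    count = 0
    block = 500
    for start in range(0, n_perm, block):
        b = min(block, n_perm - start)
        perm = np.argsort(rng.random((b, n)), axis=1)
        zp = zc[perm]
        i_perm = n / s0 * (zp[:, ii] * zp[:, jj] @ ww) / denom
        count += int((i_perm >= i_obs).sum())
    p = (1.0 + count) / (n_perm + 1.0)
    return MoranResult(I=float(i_obs), expected=-1.0 / (n - 1), p=float(p), n_permutations=n_perm)


def pearson_sampling_checks(cell_summaries: pd.DataFrame, otu_diversity: pd.DataFrame) -> pd.DataFrame:
    """Screens for sampling artifacts in the diversity summaries.

    Pearson correlations between (a) per-OTU pi and copies per OTU, and
    (b) per-cell GDM / GDE and each of total individuals, mean copies per
    OTU, and OTU richness.  A genetically well-behaved dataset shows only
    weak relationships here.  Constant inputs yield NaN rows (logged)
    rather than errors.
    """
    rows = []

    def add(name, a, b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            logger.warning("correlation %s undefined (constant or too few values)", name)
            rows.append({"pair": name, "r": np.nan, "p": np.nan, "n": int(a.size)})
            return
        res = stats.pearsonr(a, b)
        rows.append({"pair": name, "r": float(res.statistic), "p": float(res.pvalue), "n": int(a.size)})

    add("pi_vs_copies", otu_diversity["pi"], otu_diversity["n_copies"])
    cs = cell_summaries
    mean_copies = cs["n_individuals"] / cs["n_otus"]
    for metric in ("gdm", "gde"):
        add(f"{metric}_vs_individuals", cs[metric], cs["n_individuals"])
        add(f"{metric}_vs_mean_copies", cs[metric], mean_copies)
        add(f"{metric}_vs_n_otus", cs[metric], cs["n_otus"])
    return pd.DataFrame(rows)
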