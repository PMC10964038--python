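"""Partial least squares linking a regional map to gene expression.

Single-response PLS: for a univariate response the first NIPALS weight
vector is exactly the normalized centered cross-covariance X'y, so PLS1
is computed in closed form (with deflation for higher components).
Significance of the component is assessed with a spatial spin test
(random spherical rotations of the parcel centroids with one-to-one
reassignment), and per-gene reliability with bootstrap Z-scores from
region resampling with sign-aligned replicate weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .casecontrol import fdr_bh

logger = logging.getLogger(__name__)


@dataclass
class PLSResult:
    """First-component PLS fit.

    ``weights``: unit-norm gene weights of component 1; ``scores``:
    per-region component-1 scores; ``variance_explained``: fraction of
    response variance captured by component 1; ``component_variance``:
    per-component fractions; ``spin_p``: filled by the spin test;
    ``sign_flipped``: True when the component was negated to enforce
    corr(scores, y) >= 0.
    """

    weights: pd.Series
    scores: pd.Series
    variance_explained: float
    component_variance: list[float]
    sign_flipped: bool
    spin_p: float | None = None


@dataclass
class SpinNull:
    """Spin-test null distribution: per-rotation statistic values."""

    values: np.ndarray
    n_rotations: int
    seed: int


def _standardize_columns(x: np.ndarray, floor: float | None = None) -> np.ndarray:
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0, ddof=1)
    if floor is None:
        if np.any(sd == 0):
            raise ValueError("zero-variance predictor column")
        return xc / sd
    return xc / np.maximum(sd, floor)


def pls_first_component(
    X: pd.DataFrame, y: pd.Series | np.ndarray, n_components: int = 2,
    scale: bool = True,
) -> PLSResult:
    """Fit PLS of a regional map on a region x gene expression matrix.

    Predictors are column-standardized (so each gene enters on an equal
    footing; ``scale=False`` centers only) and the response is centered.
    Components follow the NIPALS
    recursion: w_k proportional to X_k'y_k, scores t_k = X_k w_k, then
    rank-one deflation. The component-1 sign is fixed so that
    corr(scores, y) >= 0. Variance explained per component is the squared
    correlation between that component's scores and the response.
    """
    y_arr = np.asarray(y, dtype=float)
    x_arr = X.to_numpy(dtype=float)
    n, n_genes = x_arr.shape
    if y_arr.shape[0] != n:
        raise ValueError("X and y have mismatched region counts")
    if n < 3:
        raise ValueError("need at least 3 regions")
    if y_arr.std() == 0:
        raise ValueError("response map has zero variance")
    max_rank = min(n - 1, n_genes)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds rank bound {max_rank}")

    if scale:
        xk = _standardize_columns(x_arr)
    else:
        xk = x_arr - x_arr.mean(axis=0)
    yc0 = y_arr - y_arr.mean()
    ss_y = float(yc0 @ yc0)
    yk = yc0.copy()

    weights1 = scores1 = None
    component_variance: list[float] = []
    for k in range(n_components):
        w = xk.T @ yk
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(f"component {k + 1} is degenerate (zero cross-covariance)")
        w /= norm
        t = xk @ w
        tt = float(t @ t)
        component_variance.append(float(t @ yc0) ** 2 / (tt * ss_y))
        if k == 0:
            weights1, scores1 = w.copy(), t.copy()
        p_load = xk.T @ t / tt
        c_load = float(t @ yk) / tt
        xk = xk - np.outer(t, p_load)
        yk = yk - c_load * t

    sign_flipped = False
    if float(scores1 @ yc0) < 0:  # enforce corr(scores, y) >= 0
        weights1, scores1, sign_flipped = -weights1, -scores1, True

    return PLSResult(
        weights=pd.Series(weights1, index=X.columns, name="weight"),
        scores=pd.Series(scores1, index=X.index, name="pls1_score"),
        variance_explained=component_variance[0],
        component_variance=component_variance,
        sign_flipped=sign_flipped,
    )


# ---------------------------------------------------------------------------
# Spin test


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation: QR of a Gaussian matrix, det fixed to +1."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _assign_greedy(dist: np.ndarray) -> np.ndarray:
    """Greedy one-to-one matching: globally nearest pairs first."""
    n = dist.shape[0]
    order = np.argsort(dist, axis=None)
    perm = np.full(n, -1, dtype=int)
    used_src = np.zeros(n, dtype=bool)
    filled = 0
    for flat in order:
        i, j = divmod(int(flat), n)
        if perm[i] >= 0 or used_src[j]:
            continue
        perm[i] = j
        used_src[j] = True
        filled += 1
        if filled == n:
            break
    return perm


def spin_permutations(
    coords: np.ndarray,
    n_rotations: int,
    seed: int = 0,
    method: str = "greedy",
) -> np.ndarray:
    """Spatial permutations from random spherical rotations.

    For each rotation, parcel centroids are rotated and each original
    parcel slot is matched one-to-one to the nearest rotated parcel
    (greedy by default; ``method='hungarian'`` uses optimal assignment).
    Returns an (n_rotations, n_regions) integer array ``perms`` such that
    a spun map is ``values[perms[r]]`` — always an exact permutation, so
    the map's value multiset is preserved.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if len(np.unique(np.round(coords, 9), axis=0)) < n:
        raise ValueError("duplicate centroids")
    rng = np.random.default_rng(seed)
    perms = np.empty((n_rotations, n), dtype=int)
    for r in range(n_rotations):
        rot = random_rotation(rng)
        rotated = coords @ rot.T
        dist = np.arccos(np.clip(coords @ rotated.T, -1.0, 1.0))
        if method == "greedy":
            perms[r] = _assign_greedy(dist)
        elif method == "hungarian":
            _, col = linear_sum_assignment(dist)
            perms[r] = col
        else:
            raise ValueError(f"unknown assignment method: {method}")
    return perms


def spin_test(
    statistic_fn,
    map_values,
    centroids: pd.DataFrame,
    n_rotations: int = 5000,
    seed: int = 0,
    method: str = "greedy",
    max_retries: int = 10,
) -> tuple[SpinNull, float]:
    """Generic spin permutation test.

    Computes ``statistic_fn(map)`` observed, then re-evaluates it on each
    spun map; p = (1 + #{null >= observed}) / (1 + n_rotations), with a
    guaranteed floor of 1/(n_rotations + 1). A statistic failure on a
    rotation is retried with a freshly drawn rotation (up to
    ``max_retries``, logged).
    """
    values = np.asarray(map_values, dtype=float)
    if values.std() == 0:
        raise ValueError("zero-variance map; spin test is degenerate")
    coords = centroids[["x", "y", "z"]].to_numpy() if isinstance(centroids, pd.DataFrame) else np.asarray(centroids)
    observed = float(statistic_fn(values))
    perms = spin_permutations(coords, n_rotations, seed=seed, method=method)
    retry_rng = np.random.default_rng(seed + 1)
    nulls = np.empty(n_rotations)
    for r in range(n_rotations):
        perm = perms[r]
        for attempt in range(max_retries + 1):
            try:
                nulls[r] = float(statistic_fn(values[perm]))
                break
            except Exception:
                if attempt == max_retries:
                    raise
                logger.warning("statistic failed on rotation %d; resampling", r)
                rot = random_rotation(retry_rng)
                dist = np.arccos(np.clip(coords @ (coords @ rot.T).T, -1.0, 1.0))
                perm = _assign_greedy(dist)
    p = (1.0 + float(np.sum(nulls >= observed))) / (1.0 + n_rotations)
    return SpinNull(values=nulls, n_rotations=n_rotations, seed=seed), p


def _batch_variance_explained(xz: np.ndarray, y_cols: np.ndarray) -> np.ndarray:
    """PLS1 variance explained for many responses against one matrix."""
    yc = y_cols - y_cols.mean(axis=0)
    w = xz.T @ yc
    t = xz @ w
    num = (t * yc).sum(axis=0) ** 2
    den = (t**2).sum(axis=0) * (yc**2).sum(axis=0)
    return num / den


def spin_test_pls(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    centroids: pd.DataFrame,
    n_rotations: int = 5000,
    seed: int = 0,
    perms: np.ndarray | None = None,
) -> tuple[SpinNull, float]:
    """Spin test of PLS1 variance explained (vectorized over rotations).

    Equivalent to :func:`spin_test` with the PLS1 variance-explained
    statistic, but evaluates all rotations in one batch of matrix
    products. ``perms`` may be supplied to reuse precomputed spatial
    permutations (the null does not depend on the response values).
    """
    y_arr = np.asarray(y, dtype=float)
    if y_arr.std() == 0:
        raise ValueError("zero-variance map; spin test is degenerate")
    if perms is None:
        coords = centroids[["x", "y", "z"]].to_numpy()
        perms = spin_permutations(coords, n_rotations, seed=seed)
    else:
        n_rotations = perms.shape[0]
    xz = _standardize_columns(X.to_numpy(dtype=float))
    observed = float(_batch_variance_explained(xz, y_arr[:, None])[0])
    nulls = _batch_variance_explained(xz, y_arr[perms].T)
    p = (1.0 + float(np.sum(nulls >= observed))) / (1.0 + n_rotations)
    return SpinNull(values=nulls, n_rotations=n_rotations, seed=seed), p


# ---------------------------------------------------------------------------
# Bootstrap gene Z-scores


def bootstrap_gene_z(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Bootstrap Z-scores for PLS1 gene weights.

    Regions are resampled with replacement ``n_boot`` times; each
    replicate's first weight vector is sign-aligned to the original (by
    the sign of their dot product, preventing SE inflation from component
    sign flips). SE per gene is the SD of aligned replicate weights;
    Z = weight / SE with two-sided normal p and BH q.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y_arr = np.asarray(y, dtype=float)
    x_arr = X.to_numpy(dtype=float)
    n = x_arr.shape[0]
    base = pls_first_component(X, y_arr, n_components=1)
    w0 = base.weights.to_numpy()

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, x_arr.shape[1]))
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            yb = y_arr[idx]
            if yb.std() > 0:
                break
            logger.warning("bootstrap replicate %d had constant response; redrawn", b)
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap replicate")
        xb = _standardize_columns(x_arr[idx], floor=1e-12)
        wb = xb.T @ (yb - yb.mean())
        wb /= np.linalg.norm(wb)
        if float(wb @ w0) < 0:
            wb = -wb
        boot[b] = wb

    se = boot.std(axis=0, ddof=1)
    se = np.maximum(se, np.finfo(float).tiny)
    z = w0 / se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    q, _ = fdr_bh(p, q_level)
    return pd.DataFrame(
        {"weight": w0, "se": se, "z": z, "p": p, "q": q},
        index=pd.Index(X.columns, name="gene_id"),
    )


def extract_pls_gene_sets(
    z_table: pd.DataFrame, z_threshold: float = 5.0, q_threshold: float = 0.05
) -> tuple[list[str], list[str]]:
    """PLS1+ / PLS1- gene sets: Z beyond +-z_threshold and q below q_threshold."""
    plus = z_table.index[(z_table["z"] > z_threshold) & (z_table["q"] < q_threshold)]
    minus = z_table.index[(z_table["z"] < -z_threshold) & (z_table["q"] < q_threshold)]
    return sorted(plus), sorted(minus)


def weights_tmap_correlation(scores: pd.Series, tmap_t: pd.Series) -> tuple[float, float]:
    """Pearson r (and p) between PLS1 region scores and the t-map.

    Under the sign convention the correlation is non-negative; a negative
    value indicates the convention was externally violated and is logged.
    """
    t = tmap_t.reindex(scores.index)
    if t.isna().any():
        raise ValueError("scores and t-map regions are not aligned")
    if len(t) < 3:
        raise ValueError("need at least 3 regions")
    r, p = stats.pearsonr(scores.to_numpy(), t.to_numpy())
    if r < 0:
        logger.warning("scores violate the sign convention (r = %.3f < 0)", r)
    return float(r), float(p)
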