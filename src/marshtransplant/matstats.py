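"""Matrix statistics and ordination.

Mantel permutation tests and ordinary-least-squares matrix regressions on
the strictly-upper-triangle entries of labelled distance matrices, the
all-pairs panel that summarises them, and non-metric multidimensional
scaling (nMDS) minimising Kruskal stress-1.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress
from skbio import DistanceMatrix

from .io import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None
    alternative: str = "greater"


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # n_samples x k, column-centred
    stress: float
    n_starts: int
    n_iterations: int
    seed: int | None
    ids: list[str] | None = None


def _as_square(m) -> np.ndarray:
    if isinstance(m, DistanceMatrix):
        return np.asarray(m.data, dtype=float)
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("expected a square matrix")
    return a


def _check_labels(a, b) -> None:
    if isinstance(a, DistanceMatrix) and isinstance(b, DistanceMatrix):
        if list(a.ids) != list(b.ids):
            raise ValidationError(
                "matrix labels differ or are ordered differently: "
                f"{list(a.ids)[:4]}... vs {list(b.ids)[:4]}..."
            )


def _upper(a: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def mantel(a, b, n_permutations: int = 999, seed: int | None = None,
           alternative: str = "greater", exhaustive: bool = False) -> MantelResult:
    """Mantel test between two distance matrices with matching labels.

    The statistic is the Pearson correlation of the strictly-upper-triangle
    entries; significance comes from jointly permuting the row/column
    labels of ``b``.  ``p = (1 + #extreme) / (1 + n_permutations)``.  With
    ``exhaustive`` (n <= 7) all ``n!`` relabellings are enumerated and the
    permutation count reported is ``n! - 1``.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    _check_labels(a, b)
    A, B = _as_square(a), _as_square(b)
    if A.shape != B.shape:
        raise ValidationError(f"matrix sizes differ: {A.shape} vs {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise ValidationError("Mantel test needs at least 3 labels")
    ua = _upper(A)
    if ua.std() == 0 or _upper(B).std() == 0:
        raise ValidationError("zero variance in upper-triangle entries")

    def corr(perm: np.ndarray) -> float:
        ub = _upper(B[np.ix_(perm, perm)])
        return float(np.corrcoef(ua, ub)[0, 1])

    r_obs = corr(np.arange(n))

    def is_extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs
        if alternative == "less":
            return r_perm <= r_obs
        return abs(r_perm) >= abs(r_obs) - 1e-12

    if exhaustive:
        if math.factorial(n) > 10_000:
            raise ValueError("exhaustive Mantel only supported for n <= 7")
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        extreme = sum(is_extreme(corr(p)) for p in perms if not np.array_equal(p, np.arange(n)))
        n_perm = len(perms) - 1
        p = (1 + extreme) / (1 + n_perm)
        return MantelResult(r_obs, p, n_perm, seed, alternative)

    rng = np.random.default_rng(seed)
    logger.debug("mantel: %d permutations, seed=%s", n_permutations, seed)
    extreme = 0
    for _ in range(n_permutations):
        if is_extreme(corr(rng.permutation(n))):
            extreme += 1
    p = (1 + extreme) / (1 + n_permutations)
    return MantelResult(r_obs, p, n_permutations, seed, alternative)


def matrix_regression(a, b) -> tuple[float, float, float]:
    """OLS of the upper triangle of ``a`` on that of predictor ``b``.

    Returns ``(slope, intercept, r_squared)``; ``r_squared`` equals the
    squared Mantel statistic for the same pair.
    """
    _check_labels(a, b)
    y, x = _upper(_as_square(a)), _upper(_as_square(b))
    if x.std() == 0:
        raise ValidationError("zero variance in predictor matrix")
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


def pairwise_panel(matrices: dict[str, DistanceMatrix], n_permutations: int = 999,
                   seed: int | None = None) -> pd.DataFrame:
    """Mantel + regression for every unordered pair of named matrices.

    Returns one row per pair with columns ``name_a, name_b, mantel_m,
    r_squared, p_value`` — the panel layout used to cross-compare
    environmental, geographic and community matrices.
    """
    if len(matrices) < 2:
        raise ValueError("panel needs at least two matrices")
    rng = np.random.default_rng(seed)
    rows = []
    for (na, ma), (nb, mb) in itertools.combinations(matrices.items(), 2):
        sub = int(rng.integers(2 ** 31)) if seed is not None else None
        res = mantel(ma, mb, n_permutations=n_permutations, seed=sub)
        _, _, r2 = matrix_regression(ma, mb)
        rows.append({"name_a": na, "name_b": nb, "mantel_m": res.r,
                     "r_squared": r2, "p_value": res.p_value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# non-metric MDS (Kruskal stress-1)
# ---------------------------------------------------------------------------

def _disparities(delta: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Monotone (isotonic) fit of configuration distances to the rank order
    of the input dissimilarities; primary tie handling (no constraint
    inside tie blocks — achieved by sorting ties by delta)."""
    dhat = np.empty_like(delta)
    dhat[order] = isotonic_regression(delta[order]).x
    return dhat


def _tie_order(d: np.ndarray, delta: np.ndarray) -> np.ndarray:
    return np.lexsort((delta, d))


def kruskal_stress(D, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    ``stress = sqrt( sum (dhat - delta)^2 / sum delta^2 )`` where ``delta``
    are configuration (Euclidean) distances and ``dhat`` their isotonic
    regression onto the rank order of ``D`` (pool-adjacent-violators).
    """
    Dm = _as_square(D)
    X = np.asarray(coordinates, dtype=float)
    if X.shape[0] != Dm.shape[0]:
        raise ValidationError("coordinate rows do not match matrix size")
    d = _upper(Dm)
    delta = pdist(X)
    if np.ptp(delta) < 1e-15:
        raise ValidationError("degenerate configuration: all pairwise distances equal")
    dhat = _disparities(delta, _tie_order(d, delta))
    return float(np.sqrt(np.sum((dhat - delta) ** 2) / np.sum(delta ** 2)))


def _classical_mds(Dm: np.ndarray, k: int) -> np.ndarray:
    n = Dm.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (Dm ** 2) @ J
    w, V = np.linalg.eigh(Bmat)
    idx = np.argsort(w)[::-1][:k]
    return V[:, idx] * np.sqrt(np.clip(w[idx], 0, None))


def _nmds_single(Dm: np.ndarray, X: np.ndarray, max_iterations: int,
                 tol: float) -> tuple[np.ndarray, float, int]:
    """One SMACOF-style nMDS run with a monotone-stress guard."""
    n = Dm.shape[0]
    d = _upper(Dm)
    it = 0
    delta = pdist(X)
    dhat = _disparities(delta, np.lexsort((delta, d)))
    stress = np.sqrt(np.sum((dhat - delta) ** 2) / np.sum(delta ** 2))
    for it in range(1, max_iterations + 1):
        # Guttman transform toward current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(delta > 0, dhat / delta, 0.0)
        R = squareform(ratio)
        Bmat = -R
        np.fill_diagonal(Bmat, R.sum(axis=1))
        X_new = Bmat @ X / n
        delta_new = pdist(X_new)
        if np.ptp(delta_new) < 1e-15:
            break
        dhat_new = _disparities(delta_new, np.lexsort((delta_new, d)))
        stress_new = np.sqrt(np.sum((dhat_new - delta_new) ** 2) / np.sum(delta_new ** 2))
        # backtrack toward the previous configuration if stress rose
        tries = 0
        while stress_new > stress and tries < 12:
            X_new = (X_new + X) / 2.0
            delta_new = pdist(X_new)
            if np.ptp(delta_new) < 1e-15:
                break
            dhat_new = _disparities(delta_new, np.lexsort((delta_new, d)))
            stress_new = np.sqrt(np.sum((dhat_new - delta_new) ** 2) / np.sum(delta_new ** 2))
            tries += 1
        if stress_new > stress:
            break
        improved = stress - stress_new
        X, delta, dhat, stress = X_new, delta_new, dhat_new, stress_new
        if improved < tol:
            break
    return X, float(stress), it


def nmds(D, k: int = 2, n_starts: int = 10, max_iterations: int = 999,
         tol: float = 1e-6, seed: int | None = None) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Runs ``n_starts`` random initial configurations plus one classical
    (metric) scaling start, iterates isotonic-regression / Guttman-update
    cycles in each, and returns the lowest-stress configuration with
    column means centred at zero.  Deterministic given ``seed``.
    """
    Dm = _as_square(D)
    n = Dm.shape[0]
    if n < k + 1:
        raise ValidationError(f"need at least {k + 1} objects for a {k}-D ordination")
    if not np.isfinite(Dm).all():
        raise ValidationError("non-finite values in the dissimilarity matrix")
    rng = np.random.default_rng(seed)
    scale = max(_upper(Dm).max(), 1e-12)
    inits = [_classical_mds(Dm, k)]
    inits += [rng.uniform(-scale, scale, size=(n, k)) for _ in range(n_starts)]
    best = None
    total_iters = 0
    for X0 in inits:
        if np.ptp(pdist(X0)) < 1e-15:
            X0 = X0 + rng.normal(scale=1e-6 * scale, size=X0.shape)
        X, stress, iters = _nmds_single(Dm, X0.copy(), max_iterations, tol)
        total_iters += iters
        if best is None or stress < best[1]:
            best = (X, stress)
    X, stress = best
    X = X - X.mean(axis=0, keepdims=True)
    # stress-1 is scale-invariant; rescale so configuration distances match
    # the input dissimilarities in RMS, purely for interpretability
    delta = pdist(X)
    if delta.max() > 0:
        X = X * np.sqrt(np.sum(_upper(Dm) ** 2) / np.sum(delta ** 2))
    ids = list(D.ids) if isinstance(D, DistanceMatrix) else None
    logger.info("nmds: k=%d, %d starts, best stress %.4f", k, len(inits), stress)
    return OrdinationResult(X, stress, len(inits), total_iters, seed, ids)
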