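"""Distance and difference matrices: community, geographic, environmental."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import ENV_VARIABLES, OTUTable, SiteEnvironment, ValidationError
from .processing import RelativeAbundanceTable

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class MatrixTransformSpec:
    """Off-diagonal transform applied to a distance matrix.

    ``natural_log`` replaces every off-diagonal entry by
    ``ln(x + pseudocount)``; the diagonal stays at zero and is excluded
    from downstream statistics anyway.
    """

    transform: str = "none"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.transform not in ("none", "natural_log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")


def bray_curtis(table: OTUTable | RelativeAbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    ``BC(i, j) = 1 - 2 * sum_k min(x_ik, x_jk) / (sum_k x_ik + sum_k x_jk)``,
    in [0, 1].  Accepts either counts (typically post-rarefaction, so all
    samples share a depth) or relative abundances.
    """
    data = table.counts if isinstance(table, OTUTable) else table.fractions
    x = np.asarray(data, dtype=float).T  # samples x OTUs
    totals = x.sum(axis=1)
    if (totals <= 0).any():
        j = int(np.argmax(totals <= 0))
        raise ValidationError(f"sample {table.sample_ids[j]!r} is all-zero")
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 samples for a dissimilarity matrix")
    mat = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(mat, ids=list(table.sample_ids))


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a 6371-km sphere, in kilometres."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(sites: Sequence[SiteEnvironment]) -> DistanceMatrix:
    """Pairwise great-circle distances between sites, in kilometres."""
    n = len(sites)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(sites[i].latitude, sites[i].longitude,
                             sites[j].latitude, sites[j].longitude)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=[s.site for s in sites])


def env_difference_matrix(sites: Sequence[SiteEnvironment], variable: str) -> DistanceMatrix:
    """Pairwise absolute differences of one environmental variable."""
    if variable not in ENV_VARIABLES:
        raise KeyError(
            f"unknown environmental variable {variable!r}; choose from {ENV_VARIABLES}"
        )
    vals = np.array([s.value(variable) for s in sites], dtype=float)
    mat = np.abs(vals[:, None] - vals[None, :])
    return DistanceMatrix(mat, ids=[s.site for s in sites])


def transform_matrix(matrix: DistanceMatrix, spec: MatrixTransformSpec) -> DistanceMatrix:
    """Apply an off-diagonal transform (e.g. natural log) to a matrix.

    The result keeps a zero diagonal but its off-diagonal entries may be
    negative (ln of values below one), so it is a matrix *shaped* like a
    distance matrix rather than a metric.
    """
    vals = np.array(matrix.data, dtype=float, copy=True)
    if spec.transform == "none":
        return DistanceMatrix(vals, ids=list(matrix.ids))
    off = ~np.eye(len(vals), dtype=bool)
    shifted = vals + spec.pseudocount
    bad = off & (shifted <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        ids = list(matrix.ids)
        raise ValidationError(
            f"cannot ln-transform non-positive entry at ({ids[i]}, {ids[j]}): "
            f"{vals[i, j]} + pseudocount {spec.pseudocount}"
        )
    vals[off] = np.log(shifted[off])
    return DistanceMatrix(vals, ids=list(matrix.ids))


def site_level_matrix(sample_matrix: DistanceMatrix,
                      site_of_sample: dict[str, str]) -> DistanceMatrix:
    """Collapse a sample-level matrix to site level by averaging blocks.

    Entry (s, t) is the mean of all sample-pair distances with one sample
    from site ``s`` and one from site ``t``; the diagonal is zero.  Useful
    for comparing community matrices with 5 x 5 site-level matrices such
    as geographic distance.
    """
    ids = list(sample_matrix.ids)
    missing = [s for s in ids if s not in site_of_sample]
    if missing:
        raise ValidationError(f"no site assignment for sample {missing[0]!r}")
    sites = sorted(set(site_of_sample[s] for s in ids))
    data = np.asarray(sample_matrix.data)
    mat = np.zeros((len(sites), len(sites)))
    for a, s in enumerate(sites):
        ia = [k for k, x in enumerate(ids) if site_of_sample[x] == s]
        for b in range(a + 1, len(sites)):
            ib = [k for k, x in enumerate(ids) if site_of_sample[x] == sites[b]]
            mat[a, b] = mat[b, a] = data[np.ix_(ia, ib)].mean()
    return DistanceMatrix(mat, ids=sites)
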