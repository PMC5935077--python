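"""Indicator-OTU scan: directional environment-change regressions.

For each OTU and each environmental variable, every sample contributes a
point ``(x, y)`` where ``x`` is the (log-scale) environmental change from
the sample's origin site to its destination site and ``y`` is the sample's
share of that OTU's total abundance across all samples.  A least-squares
regression with a two-sided t-test of the slope is run per (OTU,
variable) pair, and family-wise error is controlled by a Bonferroni
correction over all pairs tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distances import haversine_km
from .io import OTUTable, SampleMetadata, SiteEnvironment, ValidationError, site_map
from .processing import prevalence_filter, prevalence_integer_threshold

logger = logging.getLogger(__name__)

#: Variables the scan regresses against (percent carbon is excluded because
#: it is strongly collinear with nitrogen across sites).
SCAN_VARIABLES = ("air_temp", "pct_nitrogen", "salinity", "geographic_distance")

GEODIST_CONVENTIONS = ("ln1p_symmetric", "raw_symmetric")


@dataclass(frozen=True)
class ScanConfig:
    variables: tuple[str, ...] = SCAN_VARIABLES
    alpha: float = 0.001
    prevalence_min_fraction: float = 0.95
    include_classes: tuple[str, ...] = ("transplant", "replant_control", "pristine_control")
    geodist_convention: str = "ln1p_symmetric"

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValueError("scan needs at least one variable")
        for v in self.variables:
            if v not in SCAN_VARIABLES:
                raise ValueError(f"unknown scan variable {v!r}; choose from {SCAN_VARIABLES}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.geodist_convention not in GEODIST_CONVENTIONS:
            raise ValueError(f"unknown geodist convention {self.geodist_convention!r}")


@dataclass
class RegressionDataset:
    """The (x, y) cloud for one (OTU, variable) pair; one point per sample."""

    otu_id: str
    variable: str
    sample_ids: list[str]
    x: np.ndarray
    y: np.ndarray


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class ScanResult:
    otu_id: str
    variable: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    passes: bool


@dataclass
class ScanSummary:
    results: list[ScanResult]
    alpha: float
    n_otus_tested: int
    n_variables: int
    n_tests: int
    corrected_alpha: float
    n_otus_input: int
    n_tests_naive: int
    corrected_alpha_naive: float
    n_passes: int
    passing: list[tuple[str, str]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])


def env_delta(origin: str, destination: str, variable: str,
              sites, convention: str = "ln1p_symmetric") -> float:
    """Directional environmental change from origin to destination.

    For ``air_temp``, ``pct_nitrogen`` and ``salinity`` this is
    ``ln(v_destination) - ln(v_origin)`` (antisymmetric, zero for
    origin == destination).  ``geographic_distance`` is symmetric:
    ``ln(1 + d_km)`` by default (zero at zero distance), or the raw
    great-circle distance under the ``raw_symmetric`` convention.
    """
    smap = sites if isinstance(sites, dict) else site_map(sites)
    for code in (origin, destination):
        if code not in smap:
            raise ValidationError(f"unknown site {code!r}")
    o, d = smap[origin], smap[destination]
    if variable == "geographic_distance":
        dist = haversine_km(o.latitude, o.longitude, d.latitude, d.longitude)
        if convention == "ln1p_symmetric":
            return float(np.log1p(dist))
        return float(dist)
    vo, vd = o.value(variable), d.value(variable)
    if vo <= 0 or vd <= 0:
        raise ValidationError(
            f"{variable} must be positive for the ln transform "
            f"(got {vo} at {origin!r}, {vd} at {destination!r})"
        )
    return float(np.log(vd) - np.log(vo))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level after Bonferroni correction."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def linear_regression_test(x, y) -> RegressionFit:
    """OLS fit of y on x with a two-sided t-test of slope = 0 (df = n - 2).

    A perfect fit (zero residual variance) reports ``p = 0`` with the
    ``degenerate`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 points for a regression test")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in x")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return RegressionFit(0.0, float(y.mean()), 0.0, 1.0, n)
    if ss_res <= 1e-300 * ss_tot:
        return RegressionFit(float(fit.slope), float(fit.intercept), 1.0, 0.0, n,
                             degenerate=True)
    return RegressionFit(float(fit.slope), float(fit.intercept),
                         float(fit.rvalue ** 2), float(fit.pvalue), n)


def sample_deltas(metadata: list[SampleMetadata], sites, variable: str,
                  convention: str = "ln1p_symmetric",
                  sample_ids: list[str] | None = None) -> np.ndarray:
    """x values (env deltas) for a list of samples, in the given order."""
    smap = sites if isinstance(sites, dict) else site_map(sites)
    meta = {m.sample_id: m for m in metadata}
    ids = sample_ids if sample_ids is not None else [m.sample_id for m in metadata]
    return np.array([
        env_delta(meta[s].origin_site, meta[s].destination_site, variable, smap, convention)
        for s in ids
    ])


def assemble_regression_dataset(table: OTUTable, metadata: list[SampleMetadata],
                                sites, otu_id: str, variable: str,
                                config: ScanConfig = ScanConfig()) -> RegressionDataset | None:
    """Build the (x, y) dataset for one (OTU, variable) pair.

    Control samples contribute points at x = 0 (origin == destination).
    Returns ``None`` (logged, not raised) when the OTU fails the
    prevalence curation, mirroring the scan's skip behaviour.
    """
    i = table.otu_index(otu_id)
    k = prevalence_integer_threshold(table.n_samples, config.prevalence_min_fraction)
    present = int((table.counts[i, :] > 0).sum())
    if present < k:
        logger.info("OTU %s below prevalence threshold (%d < %d of %d samples); skipped",
                    otu_id, present, k, table.n_samples)
        return None
    meta = {m.sample_id: m for m in metadata}
    included = [s for s in table.sample_ids if meta[s].sample_class in config.include_classes]
    row = table.counts[i, :].astype(float)
    grand = row.sum()
    if grand <= 0:
        raise ValidationError(f"OTU {otu_id!r} has zero total count")
    shares = {s: row[j] / grand for j, s in enumerate(table.sample_ids)}
    x = sample_deltas(metadata, sites, variable, config.geodist_convention, included)
    y = np.array([shares[s] for s in included])
    return RegressionDataset(otu_id, variable, included, x, y)


def _vectorized_ols(x: np.ndarray, Y: np.ndarray):
    """Slope/intercept/R^2/two-sided p for many regressions sharing one x.

    ``Y`` is (n_otus, n_samples).  Matches scipy.stats.linregress.
    """
    n = len(x)
    xc = x - x.mean()
    sxx = float(np.sum(xc ** 2))
    ym = Y.mean(axis=1)
    Yc = Y - ym[:, None]
    sxy = Yc @ xc
    slope = sxy / sxx
    intercept = ym - slope * x.mean()
    ss_tot = np.sum(Yc ** 2, axis=1)
    ss_res = ss_tot - slope * sxy
    ss_res = np.maximum(ss_res, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        se = np.sqrt(ss_res / (n - 2) / sxx)
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(ss_tot > 0, p, 1.0)
    return slope, intercept, np.clip(r2, 0.0, 1.0), p


def run_scan(table: OTUTable, metadata: list[SampleMetadata], sites,
             config: ScanConfig = ScanConfig()) -> ScanSummary:
    """Run the full indicator-OTU scan.

    Applies the prevalence curation, regresses every surviving OTU's
    per-sample share against each variable's directional delta, and marks
    passes at the Bonferroni-corrected level
    ``alpha / (n_surviving_OTUs * n_variables)``.  The naive correction
    based on the pre-curation OTU count is reported alongside.
    """
    smap = sites if isinstance(sites, dict) else site_map(sites)
    meta = {m.sample_id: m for m in metadata}
    missing = [s for s in table.sample_ids if s not in meta]
    if missing:
        raise ValidationError(f"no metadata for sample {missing[0]!r}")
    n_input = table.n_otus
    surviving = prevalence_filter(table, config.prevalence_min_fraction)
    n_vars = len(config.variables)
    if surviving.n_otus == 0:
        logger.warning("no OTU passes the prevalence curation; scan is empty")
        return ScanSummary([], config.alpha, 0, n_vars, 0, float("nan"), n_input,
                           n_input * n_vars,
                           bonferroni_threshold(config.alpha, n_input * n_vars), 0, [])
    included = [s for s in surviving.sample_ids
                if meta[s].sample_class in config.include_classes]
    if len(included) < 3:
        raise ValidationError("fewer than 3 samples in the included classes")
    counts = surviving.counts.astype(float)
    grand = counts.sum(axis=1)
    shares = counts / grand[:, None]  # grand totals over ALL samples
    col = [surviving.sample_ids.index(s) for s in included]
    Y = shares[:, col]
    n_tests = surviving.n_otus * n_vars
    corrected = bonferroni_threshold(config.alpha, n_tests)
    n_tests_naive = n_input * n_vars
    corrected_naive = bonferroni_threshold(config.alpha, n_tests_naive)
    results: list[ScanResult] = []
    for var in config.variables:
        x = sample_deltas(metadata, smap, var, config.geodist_convention, included)
        if np.ptp(x) == 0:
            raise ValidationError(f"variable {var!r} has zero variance across samples")
        slope, intercept, r2, p = _vectorized_ols(x, Y)
        for i, otu in enumerate(surviving.otu_ids):
            results.append(ScanResult(otu, var, float(slope[i]), float(intercept[i]),
                                      float(r2[i]), float(p[i]), len(included),
                                      bool(p[i] < corrected)))
    results.sort(key=lambda r: (r.p_value, r.otu_id, r.variable))
    passing = [(r.otu_id, r.variable) for r in results if r.passes]
    logger.info("scan: %d OTUs x %d variables = %d tests; corrected alpha %.3g; %d passes",
                surviving.n_otus, n_vars, n_tests, corrected, len(passing))
    return ScanSummary(results, config.alpha, surviving.n_otus, n_vars, n_tests,
                       corrected, n_input, n_tests_naive, corrected_naive,
                       len(passing), passing)
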