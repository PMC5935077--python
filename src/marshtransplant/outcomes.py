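"""Transplant-outcome classification.

Four qualitative outcomes are possible for a transplanted community
relative to the undisturbed communities of its origin and destination
sites: it can look unchanged (``no_change``), look like the destination
(``total_adoption``), sit between the two (``host_shift``), or end up far
from both (``random_shift``).  This module formalises those outcomes as a
deterministic rule over Bray-Curtis distances to the pristine-control
clouds of each site.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io import SampleMetadata, ValidationError

logger = logging.getLogger(__name__)

OUTCOMES = ("no_change", "total_adoption", "host_shift", "random_shift")


@dataclass(frozen=True)
class OutcomeThresholds:
    """``tau`` scales each site's control dispersion into a tolerance band:
    a transplant within ``tau * baseline`` of a control cloud is considered
    indistinguishable from it."""

    tau: float = 1.5

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")


@dataclass
class ControlStatistics:
    """Reference geometry of the control clouds.

    ``baseline[s]`` is the mean pairwise Bray-Curtis among site ``s``'s
    controls; ``separation[(s, t)]`` the mean Bray-Curtis between the
    controls of sites ``s`` and ``t`` (keyed by sorted pair).
    """

    members: dict[str, list[str]]
    baseline: dict[str, float]
    separation: dict[tuple[str, str], float]

    def sep(self, s: str, t: str) -> float:
        return self.separation[tuple(sorted((s, t)))]


@dataclass(frozen=True)
class OutcomeCall:
    sample_id: str
    origin_site: str
    destination_site: str
    call: str
    d_origin: float
    d_destination: float
    baseline_origin: float
    baseline_destination: float
    separation: float


_CONTROL_CLASSES = {
    "pristine": ("pristine_control",),
    "both": ("pristine_control", "replant_control"),
}


def control_statistics(bc: DistanceMatrix, metadata: list[SampleMetadata],
                       controls: str = "pristine") -> ControlStatistics:
    """Baselines and separations of the per-site control clouds.

    Every site referenced by a transplant sample must have at least two
    control samples in the matrix.
    """
    if controls not in _CONTROL_CLASSES:
        raise ValueError(f"controls must be one of {sorted(_CONTROL_CLASSES)}")
    classes = _CONTROL_CLASSES[controls]
    ids = set(bc.ids)
    members: dict[str, list[str]] = {}
    referenced: set[str] = set()
    for m in metadata:
        if m.sample_id not in ids:
            continue
        if m.sample_class in classes:
            members.setdefault(m.origin_site, []).append(m.sample_id)
        elif m.sample_class == "transplant":
            referenced.update((m.origin_site, m.destination_site))
    for site in sorted(referenced):
        if len(members.get(site, [])) < 2:
            raise ValidationError(
                f"site {site!r} has fewer than 2 {'/'.join(classes)} samples; "
                "cannot form a control cloud"
            )
    baseline = {}
    for site, samp in members.items():
        if len(samp) < 2:
            continue
        baseline[site] = float(np.mean([bc[a, b] for a, b in combinations(samp, 2)]))
    separation = {}
    for s, t in combinations(sorted(baseline), 2):
        separation[(s, t)] = float(np.mean(
            [bc[a, b] for a in members[s] for b in members[t]]
        ))
    return ControlStatistics(members, baseline, separation)


def classify_outcome(sample_id: str, bc: DistanceMatrix,
                     metadata: list[SampleMetadata],
                     stats: ControlStatistics | None = None,
                     thresholds: OutcomeThresholds = OutcomeThresholds(),
                     controls: str = "pristine") -> OutcomeCall:
    """Classify one transplant sample.

    With ``d_o``/``d_d`` the mean Bray-Curtis from the sample to the
    origin/destination control clouds and tolerance bands
    ``eps = tau * baseline``:

    - ``no_change``       if ``d_o <= eps_o`` and ``d_o <= d_d``;
    - ``total_adoption``  if ``d_d <= eps_d`` and ``d_d < d_o``;
    - ``host_shift``      otherwise, if ``max(d_o, d_d)`` does not exceed
      the origin/destination control separation (the sample lies between
      the clouds);
    - ``random_shift``    otherwise.
    """
    meta = {m.sample_id: m for m in metadata}
    if sample_id not in meta:
        raise ValidationError(f"unknown sample {sample_id!r}")
    m = meta[sample_id]
    if m.sample_class != "transplant":
        raise ValidationError(f"sample {sample_id!r} is a {m.sample_class}, not a transplant")
    if stats is None:
        stats = control_statistics(bc, metadata, controls)
    for site in (m.origin_site, m.destination_site):
        if site not in stats.baseline:
            raise ValidationError(f"no control statistics for site {site!r}")
    d_o = float(np.mean([bc[sample_id, c] for c in stats.members[m.origin_site]]))
    d_d = float(np.mean([bc[sample_id, c] for c in stats.members[m.destination_site]]))
    eps_o = thresholds.tau * stats.baseline[m.origin_site]
    eps_d = thresholds.tau * stats.baseline[m.destination_site]
    sep = stats.sep(m.origin_site, m.destination_site)
    if d_o <= eps_o and d_o <= d_d:
        call = "no_change"
    elif d_d <= eps_d and d_d < d_o:
        call = "total_adoption"
    elif max(d_o, d_d) <= sep:
        call = "host_shift"
    else:
        call = "random_shift"
    return OutcomeCall(sample_id, m.origin_site, m.destination_site, call,
                       d_o, d_d, stats.baseline[m.origin_site],
                       stats.baseline[m.destination_site], sep)


def classify_all(bc: DistanceMatrix, metadata: list[SampleMetadata],
                 thresholds: OutcomeThresholds = OutcomeThresholds(),
                 controls: str = "pristine") -> list[OutcomeCall]:
    """Classify every transplant sample present in the matrix."""
    stats = control_statistics(bc, metadata, controls)
    ids = set(bc.ids)
    return [
        classify_outcome(m.sample_id, bc, metadata, stats, thresholds)
        for m in metadata
        if m.sample_class == "transplant" and m.sample_id in ids
    ]


def outcome_summary(calls: list[OutcomeCall]) -> pd.DataFrame:
    """Tabulate calls per (origin, destination) design cell.

    Returns one row per cell with per-outcome counts and the modal call
    (``"tie"`` when no single outcome dominates).
    """
    if not calls:
        raise ValueError("no outcome calls to summarise")
    cells: dict[tuple[str, str], Counter] = {}
    for c in calls:
        cells.setdefault((c.origin_site, c.destination_site), Counter())[c.call] += 1
    rows = []
    for (o, d), counter in sorted(cells.items()):
        top = counter.most_common()
        modal = top[0][0] if len(top) == 1 or top[0][1] > top[1][1] else "tie"
        row = {"origin_site": o, "destination_site": d, "n": sum(counter.values()),
               "modal_call": modal}
        for outcome in OUTCOMES:
            row[f"n_{outcome}"] = counter.get(outcome, 0)
        rows.append(row)
    return pd.DataFrame(rows)
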