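"""Tabular input/output and the core labelled data containers.

All interchange is plain tab-separated text: OTU count tables
(OTUs x samples, optional trailing ``taxonomy`` column), per-sample
transplant metadata, per-site environment tables and square labelled
distance matrices.  Validation happens at the boundary so that the
analysis modules can assume well-formed inputs; every error message
names the offending label or cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

SAMPLE_CLASSES = ("transplant", "replant_control", "pristine_control")

#: Environmental variables measured per site (Table-1 style schema).
ENV_VARIABLES = ("pct_nitrogen", "pct_carbon", "salinity", "air_temp")


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class OTUTable:
    """Non-negative integer OTU x sample count matrix with labels.

    Parameters
    ----------
    otu_ids :
        Unique OTU identifiers, one per matrix row.
    sample_ids :
        Unique sample identifiers, one per matrix column.
    counts :
        Integer array of shape ``(len(otu_ids), len(sample_ids))``.
    taxonomy :
        Optional semicolon-delimited lineage string per OTU.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.otu_ids)} OTU ids x {len(self.sample_ids)} sample ids"
            )
        _check_unique(self.otu_ids, "OTU id")
        _check_unique(self.sample_ids, "sample id")
        # a filter may legitimately remove every OTU; zero samples is an error
        if len(self.sample_ids) == 0:
            raise ValidationError("OTU table has no samples")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-9):
                i, j = np.argwhere(~np.isclose(self.counts, rounded))[0]
                raise ValidationError(
                    f"non-integer count at ({self.otu_ids[i]}, {self.sample_ids[j]})"
                )
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at ({self.otu_ids[i]}, {self.sample_ids[j]})"
            )
        if self.taxonomy is not None and len(self.taxonomy) != len(self.otu_ids):
            raise ValidationError("taxonomy length does not match number of OTUs")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def otu_totals(self) -> np.ndarray:
        """Total count of each OTU across all samples."""
        return self.counts.sum(axis=1)

    def sample_totals(self) -> np.ndarray:
        """Total count (sequencing depth) of each sample."""
        return self.counts.sum(axis=0)

    def otu_index(self, otu_id: str) -> int:
        try:
            return self.otu_ids.index(otu_id)
        except ValueError:
            raise KeyError(f"unknown OTU id {otu_id!r}") from None

    def select_otus(self, keep: Sequence[int]) -> "OTUTable":
        keep = list(keep)
        tax = [self.taxonomy[i] for i in keep] if self.taxonomy is not None else None
        return OTUTable(
            [self.otu_ids[i] for i in keep], list(self.sample_ids),
            self.counts[keep, :], tax,
        )

    def select_samples(self, keep_ids: Sequence[str]) -> "OTUTable":
        idx = [self.sample_ids.index(s) for s in keep_ids]
        return OTUTable(
            list(self.otu_ids), [self.sample_ids[i] for i in idx],
            self.counts[:, idx], list(self.taxonomy) if self.taxonomy else None,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)
        df.index.name = "otu_id"
        return df


@dataclass(frozen=True)
class SampleMetadata:
    """One record of the transplant design: where a core came from and went."""

    sample_id: str
    origin_site: str
    destination_site: str
    sample_class: str
    replicate: int = 1

    def __post_init__(self) -> None:
        cls = self.sample_class.strip().lower()
        object.__setattr__(self, "sample_class", cls)
        if cls not in SAMPLE_CLASSES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown sample class {cls!r}; "
                f"allowed values are {', '.join(SAMPLE_CLASSES)}"
            )
        if cls in ("replant_control", "pristine_control") and (
            self.origin_site != self.destination_site
        ):
            raise ValidationError(
                f"sample {self.sample_id!r}: {cls} requires origin == destination "
                f"(got {self.origin_site!r} -> {self.destination_site!r})"
            )


@dataclass(frozen=True)
class SiteEnvironment:
    """Coordinates and environmental measurements of one marsh site.

    Longitude is stored signed (west negative).  Environmental values must
    be strictly positive so that natural-log transforms are defined.
    """

    site: str
    latitude: float
    longitude: float
    pct_nitrogen: float
    pct_carbon: float
    salinity: float
    air_temp: float

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValidationError(f"site {self.site!r}: latitude {self.latitude} out of range")
        if not -180 <= self.longitude <= 180:
            raise ValidationError(f"site {self.site!r}: longitude {self.longitude} out of range")
        for var in ENV_VARIABLES:
            v = getattr(self, var)
            if not v > 0:
                raise ValidationError(
                    f"site {self.site!r}: {var} = {v} must be strictly positive "
                    "(natural-log transform would be undefined)"
                )

    def value(self, variable: str) -> float:
        if variable not in ENV_VARIABLES:
            raise KeyError(f"unknown environmental variable {variable!r}")
        return float(getattr(self, variable))


def site_map(sites: Iterable[SiteEnvironment]) -> dict[str, SiteEnvironment]:
    out: dict[str, SiteEnvironment] = {}
    for s in sites:
        if s.site in out:
            raise ValidationError(f"duplicate site code {s.site!r}")
        out[s.site] = s
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} {lab!r}")
        seen.add(lab)


def read_otu_table(path: str | Path, orientation: str = "otus_as_rows") -> OTUTable:
    """Read a tab-separated OTU count table.

    ``orientation`` is ``otus_as_rows`` or ``samples_as_rows``; the result
    is always normalised to OTUs-as-rows.  A trailing ``taxonomy`` column
    (OTUs-as-rows only) is captured as lineage strings.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "column label")  # before pandas mangles duplicates
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ValidationError(f"{path}: empty table")
    taxonomy = None
    if orientation == "otus_as_rows" and df.columns[-1].strip().lower() == "taxonomy":
        taxonomy = df.iloc[:, -1].fillna("").tolist()
        df = df.iloc[:, :-1]
    if df.empty:
        raise ValidationError(f"{path}: table has no count columns")
    row_ids = [str(r) for r in df.index]
    col_ids = [str(c) for c in df.columns]
    _check_unique(row_ids, "row label")
    _check_unique(col_ids, "column label")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                val = int(str(raw).strip())
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: cannot parse count {raw!r} at ({row_ids[i]}, {col_ids[j]})"
                ) from None
            if val < 0:
                raise ValidationError(
                    f"{path}: negative count {val} at ({row_ids[i]}, {col_ids[j]})"
                )
            counts[i, j] = val
    if orientation == "samples_as_rows":
        counts = counts.T
        row_ids, col_ids = col_ids, row_ids
    return OTUTable(row_ids, col_ids, counts, taxonomy)


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    df = table.to_dataframe()
    if table.taxonomy is not None:
        df = df.assign(taxonomy=table.taxonomy)
    df.to_csv(path, sep="\t")


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample transplant metadata; warns on incomplete designs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "origin_site", "destination_site", "sample_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(SampleMetadata(
            sample_id=str(row["sample_id"]).strip(),
            origin_site=str(row["origin_site"]).strip(),
            destination_site=str(row["destination_site"]).strip(),
            sample_class=str(row["sample_class"]).strip().lower(),
            replicate=int(row.get("replicate", 1) or 1),
        ))
    _check_unique([r.sample_id for r in records], "sample id")
    _warn_incomplete_design(records)
    return records


def _warn_incomplete_design(records: Sequence[SampleMetadata]) -> None:
    """Log a warning when the factorial transplant design has missing cells."""
    non_pristine = [r for r in records if r.sample_class != "pristine_control"]
    if not non_pristine:
        return
    sites = sorted({r.origin_site for r in non_pristine} | {r.destination_site for r in non_pristine})
    reps_per_cell: dict[tuple[str, str], int] = {}
    for r in non_pristine:
        key = (r.origin_site, r.destination_site)
        reps_per_cell[key] = reps_per_cell.get(key, 0) + 1
    max_reps = max(reps_per_cell.values())
    missing = []
    for o in sites:
        for d in sites:
            n = reps_per_cell.get((o, d), 0)
            if n < max_reps:
                missing.append(f"{o}->{d} ({n}/{max_reps})")
    if missing:
        logger.warning(
            "transplant design is not fully factorial; short cells: %s",
            ", ".join(missing),
        )


def write_sample_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame([
        {
            "sample_id": r.sample_id, "origin_site": r.origin_site,
            "destination_site": r.destination_site,
            "sample_class": r.sample_class, "replicate": r.replicate,
        }
        for r in records
    ]).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[SiteEnvironment]:
    """Read a per-site environment table.

    Longitude may be given either signed (column ``longitude``, west
    negative) or as positive degrees west (column ``longitude_w``); it is
    always stored signed.
    """
    df = pd.read_csv(path, sep="\t")
    if "site" not in df.columns:
        raise ValidationError(f"{path}: missing 'site' column")
    if "longitude_w" in df.columns:
        lon = -df["longitude_w"].astype(float)
    elif "longitude" in df.columns:
        lon = df["longitude"].astype(float)
    else:
        raise ValidationError(f"{path}: need a 'longitude' or 'longitude_w' column")
    needed = ["latitude", *ENV_VARIABLES]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing site columns {missing}")
    sites = []
    for i, row in df.iterrows():
        code = str(row["site"]).strip()
        if not code or code.lower() == "nan":
            raise ValidationError(f"{path}: missing site code in row {i}")
        sites.append(SiteEnvironment(
            site=code,
            latitude=float(row["latitude"]),
            longitude=float(lon.iloc[i]),
            pct_nitrogen=float(row["pct_nitrogen"]),
            pct_carbon=float(row["pct_carbon"]),
            salinity=float(row["salinity"]),
            air_temp=float(row["air_temp"]),
        ))
    site_map(sites)  # uniqueness check
    return sites


def write_site_table(sites: Sequence[SiteEnvironment], path: str | Path) -> None:
    pd.DataFrame([
        {
            "site": s.site, "latitude": s.latitude, "longitude": s.longitude,
            "pct_nitrogen": s.pct_nitrogen, "pct_carbon": s.pct_carbon,
            "salinity": s.salinity, "air_temp": s.air_temp,
        }
        for s in sites
    ]).to_csv(path, sep="\t", index=False)


def paper_sites() -> list[SiteEnvironment]:
    """The packaged five-marsh US East Coast site table (WB, PI, JR, RC, AB)."""
    ref = resources.files("marshtransplant").joinpath("data/table1_sites.tsv")
    with resources.as_file(ref) as p:
        return read_site_table(p)


#: North/south regional grouping of the packaged five-marsh design.
PAPER_REGIONS = {"WB": "north", "PI": "north", "JR": "south", "RC": "south", "AB": "south"}


def read_distance_matrix(path: str | Path, tol: float = 1e-9) -> DistanceMatrix:
    """Read a square labelled TSV matrix, validating symmetry and zero diagonal."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != labels:
        raise ValidationError(f"{path}: row and column labels differ")
    values = df.to_numpy(dtype=float)
    asym = np.abs(values - values.T)
    if asym.max() > tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValidationError(
            f"{path}: matrix asymmetric at ({labels[i]}, {labels[j]}): "
            f"{values[i, j]} vs {values[j, i]}"
        )
    diag = np.abs(np.diag(values))
    if diag.max() > tol:
        i = int(np.argmax(diag))
        raise ValidationError(f"{path}: nonzero diagonal at {labels[i]}: {values[i, i]}")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, ids=labels)


def write_distance_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(matrix.data, dtype=float),
                      index=list(matrix.ids), columns=list(matrix.ids))
    df.to_csv(path, sep="\t")
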