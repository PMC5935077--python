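"""OTU-table transformations applied ahead of the community statistics.

The canonical order for a transplant dataset is: rarefy every sample to a
common depth (sampling without replacement), drop singletons (OTUs with a
grand total of one read), and only then compute relative abundances,
top-N subsets or prevalence-curated OTU sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import OTUTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RelativeAbundanceTable:
    """Per-sample OTU fractions; each sample column sums to one."""

    otu_ids: list[str]
    sample_ids: list[str]
    fractions: np.ndarray
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        sums = self.fractions.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            j = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"sample {self.sample_ids[j]!r}: fractions sum to {sums[j]}, not 1"
            )


def rarefy(table: OTUTable, depth: int, seed: int | None = None,
           drop_shallow: bool = False) -> OTUTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Each sample's reads are subsampled uniformly at random (multivariate
    hypergeometric), so per-sample totals afterwards all equal ``depth``.
    Samples with fewer than ``depth`` reads raise an error, or are removed
    with a warning when ``drop_shallow`` is set.  OTU rows that become
    all-zero are retained (a later filter may remove them).
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    logger.info("rarefying %d samples to depth %d (seed=%s)", table.n_samples, depth, seed)
    totals = table.sample_totals()
    shallow = [table.sample_ids[j] for j in np.nonzero(totals < depth)[0]]
    if shallow and not drop_shallow:
        raise ValidationError(
            f"sample {shallow[0]!r} has fewer than {depth} reads "
            f"({int(totals[table.sample_ids.index(shallow[0])])}); "
            "use drop_shallow to remove such samples instead"
        )
    keep_ids = [s for s in table.sample_ids if s not in shallow]
    if shallow:
        logger.warning("dropping %d shallow samples: %s", len(shallow), ", ".join(shallow))
    out = np.zeros((table.n_otus, len(keep_ids)), dtype=np.int64)
    for j, sid in enumerate(keep_ids):
        col = table.counts[:, table.sample_ids.index(sid)]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return OTUTable(list(table.otu_ids), keep_ids, out,
                    list(table.taxonomy) if table.taxonomy else None)


def remove_singletons(table: OTUTable) -> tuple[OTUTable, int]:
    """Drop OTUs whose total count across all samples is exactly one."""
    totals = table.otu_totals()
    keep = np.nonzero(totals != 1)[0]
    n_removed = table.n_otus - len(keep)
    logger.info("singleton filter: %d OTUs in, %d removed, %d kept",
                table.n_otus, n_removed, len(keep))
    return table.select_otus(keep), n_removed


def relative_abundance(table: OTUTable) -> RelativeAbundanceTable:
    """Convert counts to within-sample fractions."""
    totals = table.sample_totals()
    if (totals == 0).any():
        j = int(np.argmax(totals == 0))
        raise ValidationError(f"sample {table.sample_ids[j]!r} has zero total count")
    return RelativeAbundanceTable(
        list(table.otu_ids), list(table.sample_ids),
        table.counts / totals[np.newaxis, :],
        list(table.taxonomy) if table.taxonomy else None,
    )


def top_n_otus(table: OTUTable, n: int) -> OTUTable:
    """Keep the ``n`` OTUs with the largest grand totals.

    Ties at the boundary are broken lexicographically on OTU id (and
    logged), so the result is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= table.n_otus:
        if n > table.n_otus:
            logger.warning("top_n_otus: n=%d exceeds OTU count %d; returning full table",
                           n, table.n_otus)
        return table.select_otus(range(table.n_otus))
    totals = table.otu_totals()
    order = sorted(range(table.n_otus), key=lambda i: (-totals[i], table.otu_ids[i]))
    boundary = totals[order[n - 1]]
    if sum(1 for t in totals if t == boundary) > 1:
        logger.info("top_n_otus: tie at total=%d broken lexicographically", boundary)
    keep = sorted(order[:n])  # preserve original row order
    return table.select_otus(keep)


def prevalence_integer_threshold(n_samples: int, min_fraction: float) -> int:
    """Smallest k with k / n_samples strictly greater than ``min_fraction``."""
    k = int(np.floor(min_fraction * n_samples)) + 1
    while (k - 1) / n_samples > min_fraction:  # guard float edge cases
        k -= 1
    return k


def prevalence_filter(table: OTUTable, min_fraction: float) -> OTUTable:
    """Keep OTUs present (nonzero) in strictly more than ``min_fraction`` of samples."""
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    k = prevalence_integer_threshold(table.n_samples, min_fraction)
    present = (table.counts > 0).sum(axis=1)
    keep = np.nonzero(present >= k)[0]
    logger.info("prevalence filter (> %.0f%% of %d samples, i.e. >= %d): %d of %d OTUs kept",
                100 * min_fraction, table.n_samples, k, len(keep), table.n_otus)
    return table.select_otus(keep)


def aggregate_display_taxa(rel: RelativeAbundanceTable, rank: int,
                           min_any_sample: float = 0.05,
                           taxonomy: list[str] | None = None) -> RelativeAbundanceTable:
    """Sum OTU fractions by lineage at ``rank``; pool minor taxa into "other".

    A taxon is displayed only if its summed fraction reaches
    ``min_any_sample`` in at least one sample; everything else is pooled
    into an ``other`` row.  Missing lineages or ranks map to
    ``unclassified``.  Column sums remain one.
    """
    tax = taxonomy if taxonomy is not None else rel.taxonomy
    if tax is None:
        raise ValueError("taxonomy required: none stored on the table or passed in")
    names = []
    for lineage in tax:
        parts = [p.strip() for p in str(lineage or "").split(";") if p.strip()]
        names.append(parts[rank] if rank < len(parts) else "unclassified")
    taxa = sorted(set(names))
    summed = np.zeros((len(taxa), len(rel.sample_ids)))
    for i, name in enumerate(names):
        summed[taxa.index(name), :] += rel.fractions[i, :]
    shown = [t for i, t in enumerate(taxa) if summed[i].max() >= min_any_sample]
    hidden = [t for t in taxa if t not in shown]
    rows = [summed[taxa.index(t)] for t in shown]
    out_ids = list(shown)
    if hidden:
        rows.append(sum(summed[taxa.index(t)] for t in hidden))
        out_ids.append("other")
    return RelativeAbundanceTable(out_ids, list(rel.sample_ids), np.vstack(rows))


def otu_percent_of_total(table: OTUTable, otu_id: str) -> np.ndarray:
    """Share of one OTU's grand total contributed by each sample.

    ``share_s = count(otu, s) / sum_s' count(otu, s')``; shares sum to one
    across samples.  This is the dependent variable of the indicator scan
    (a proportion; multiply by 100 for percent).
    """
    row = table.counts[table.otu_index(otu_id), :].astype(float)
    total = row.sum()
    if total <= 0:
        raise ValidationError(f"OTU {otu_id!r} has zero total count")
    return row / total
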