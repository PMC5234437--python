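"""Depth normalization of OTU count tables.

The default normalization rescales each sample's counts by
``min_depth / sample_depth`` — i.e. divides by the library size and
multiplies by the smallest library size — so all samples carry the depth
of the shallowest one without any random subsampling or data loss.
Classical rarefaction (random subsampling without replacement) is offered
as an alternative.  Normalized values stay real-valued: the alpha-diversity
step applies its own 0.5-count floor, and rounding here would apply a
threshold twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable, NormalizedTable, RelAbundanceTable, ValidationError


def normalize_counts(table: CountTable) -> NormalizedTable:
    """Rescale every sample to the depth of the shallowest sample.

    n_ij = c_ij * min_k(S_k) / S_j, with S_j the total of sample j.
    Deterministic; preserves within-sample proportions exactly.
    """
    sums = table.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(f"samples with zero total reads: {list(zero.index)}")
    min_depth = float(sums.min())
    values = table.counts.astype(float) * (min_depth / sums)
    return NormalizedTable(values=values, taxonomy=table.taxonomy, min_depth=min_depth)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each sample's reads are treated as a finite population and a uniform
    subset of size ``depth`` is drawn (multivariate hypergeometric), so a
    fixed seed reproduces the draw bit-identically.
    """
    if depth <= 0:
        raise ValidationError("rarefaction depth must be positive")
    sums = table.sample_sums()
    under = sums[sums < depth]
    if len(under):
        raise ValidationError(
            f"samples with fewer than {depth} reads: {dict(under)}"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index)[table.sample_ids]
    return CountTable(counts=counts, taxonomy=table.taxonomy)


def to_relative(table: CountTable | NormalizedTable) -> RelAbundanceTable:
    """Convert counts (raw or normalized) to percentages per sample."""
    values = table.counts.astype(float) if isinstance(table, CountTable) else table.values
    sums = values.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(f"samples with zero total: {list(zero.index)}")
    rel = 100.0 * values / sums
    return RelAbundanceTable(values=rel, taxonomy=table.taxonomy)


@dataclass
class DepthReport:
    totals: pd.Series
    flagged: list
    fraction: float
    median_depth: float


def depth_report(table: CountTable, fraction: float = 0.1) -> DepthReport:
    """Per-sample totals plus a shallow-sample flag list.

    A sample is flagged when its total is below ``fraction`` of the median
    depth (default 1/10 — e.g. a 2,000-read sample among ~20,000-read
    libraries).  Flagged samples are never auto-removed: deciding whether a
    shallow library reflects experimental failure is the user's call.
    """
    totals = table.sample_sums().astype(float)
    median = float(totals.median())
    # boundary inclusive: a 2,000-read sample among 20,000-read libraries is
    # exactly at the default 1/10 fraction and is the canonical flag case
    flagged = [] if fraction <= 0 else list(totals.index[totals <= fraction * median])
    return DepthReport(totals=totals, flagged=flagged, fraction=fraction, median_depth=median)
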