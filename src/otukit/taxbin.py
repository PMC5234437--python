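"""Aggregation of OTU relative abundances at higher taxonomic ranks.

At every rank, OTUs sharing the same lineage prefix are summed.  OTUs of
unknown placement at the target rank but with a known higher-rank root are
kept apart by that root: the bin label is the deepest known prefix padded
with ``Unknown`` to the rank depth (e.g. ``Bacteria;Firmicutes;Unknown``),
so unknowns under different roots never merge into one "unclassified"
pool.  Ranks are positional (column index in the split lineage, expected
depth 6, kingdom..genus); shorter lineages are padded with unknowns.
"""

from __future__ import annotations

import pandas as pd

from .io import N_RANKS, RANK_NAMES, RelAbundanceTable

UNKNOWN = "Unknown"


def _rank_index(rank: str | int) -> int:
    if isinstance(rank, int):
        if not 0 <= rank < N_RANKS:
            raise ValueError(f"rank index out of range: {rank}")
        return rank
    try:
        return RANK_NAMES.index(rank)
    except ValueError:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANK_NAMES}") from None


def bin_label(lineage: list[str], rank_idx: int) -> str:
    """Lineage-prefix label at a rank, unknowns padded by deepest known root."""
    padded = [(x if x else UNKNOWN) for x in lineage[: rank_idx + 1]]
    padded += [UNKNOWN] * (rank_idx + 1 - len(padded))
    # collapse a run of trailing unknowns to one terminal Unknown so that
    # "Bacteria;;" and "Bacteria;" agree at every rank below the known root
    while len(padded) > 1 and padded[-1] == UNKNOWN and padded[-2] == UNKNOWN:
        padded.pop()
    return ";".join(padded)


def bin_at_rank(rel: RelAbundanceTable, rank: str | int) -> pd.DataFrame:
    """Sum relative abundances over all OTUs sharing a lineage prefix.

    Returns bins x samples percentages; per-sample sums equal the input
    sums exactly (every OTU lands in exactly one bin).
    """
    if rel.taxonomy is None:
        raise ValueError("binning needs per-OTU taxonomy")
    idx = _rank_index(rank)
    labels = pd.Series(
        [bin_label(list(rel.taxonomy[o]), idx) for o in rel.otu_ids],
        index=rel.values.index,
    )
    binned = rel.values.groupby(labels).sum()
    return binned[rel.values.columns]


def bin_all_ranks(rel: RelAbundanceTable, ranks=RANK_NAMES) -> dict[str, pd.DataFrame]:
    return {str(r): bin_at_rank(rel, r) for r in ranks}
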