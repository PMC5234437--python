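"""Within-sample (alpha) diversity: richness, Shannon, Simpson and their
effective numbers.

Diversity indices are reported together with their effective numbers
(Hill numbers): the number of equally abundant species that would produce
the same index value.  Effective Shannon is exp(H) (order-1 Hill number)
and effective Simpson is 1/D (order-2 Hill number, the inverse Simpson
index), so a uniform community of S species scores S on all three scales
and values are comparable across indices.

Because the input is a depth-normalized table, OTUs at or below a 0.5
normalized-count floor are treated as absent throughout — such fractional
counts are likely artifacts of rescaling unequal depths.  The floor is
applied uniformly before computing proportions, so richness, H and D all
describe the same filtered community.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import NormalizedTable

DEFAULT_FLOOR = 0.5


def richness(sample: np.ndarray, floor: float = DEFAULT_FLOOR) -> int:
    """Number of OTUs with normalized count strictly above ``floor``."""
    sample = np.asarray(sample, dtype=float)
    return int((sample > floor).sum())


def shannon(p: np.ndarray) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log) over p_i > 0."""
    p = np.asarray(p, dtype=float)
    if p.sum() <= 0:
        raise ValueError("all-zero proportion vector")
    p = p / p.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def simpson(p: np.ndarray) -> float:
    """Simpson concentration D = sum p_i^2."""
    p = np.asarray(p, dtype=float)
    if p.sum() <= 0:
        raise ValueError("all-zero proportion vector")
    p = p / p.sum()
    return float((p**2).sum())


def effective_numbers(h: float, d: float) -> tuple[float, float]:
    """Effective Shannon exp(H) and effective (inverse) Simpson 1/D."""
    if d <= 0:
        raise ValueError("Simpson index must be positive")
    return float(np.exp(h)), float(1.0 / d)


def alpha_table(table: NormalizedTable, floor: float = DEFAULT_FLOOR) -> pd.DataFrame:
    """Per-sample alpha-diversity summary.

    Returns one row per sample with columns richness, shannon, simpson,
    eff_shannon, eff_simpson.  Proportions are computed over the OTUs that
    pass the richness floor, so all five quantities describe the same
    community.
    """
    rows = {}
    for sample in table.sample_ids:
        col = table.values[sample].to_numpy(dtype=float)
        kept = col[col > floor]
        s = richness(col, floor)
        if s == 0:
            rows[sample] = dict(
                richness=0, shannon=np.nan, simpson=np.nan,
                eff_shannon=np.nan, eff_simpson=np.nan,
            )
            continue
        h = shannon(kept)
        d = simpson(kept)
        eff_h, eff_d = effective_numbers(h, d)
        rows[sample] = dict(
            richness=s, shannon=h, simpson=d, eff_shannon=eff_h, eff_simpson=eff_d
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out.loc[table.sample_ids]
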