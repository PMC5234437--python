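"""Correlations between meta-variables and CLR-transformed taxonomic variables.

Relative abundances are compositional: an independent change in one
community member moves every other member's proportion, so Pearson
correlations on raw proportions are confounded.  The centred log-ratio
(CLR) transform, clr_i = ln(p_i / g) with g the geometric mean of the
sample's proportions, removes this closure constraint.  Here the geometric
mean runs over the *detected* taxa only (zeros were already converted to
missing upstream, mirroring the zero-as-missing philosophy rather than
imputing a pseudocount); an optional pseudocount restores the conventional
all-taxa CLR.

Pipeline for taxonomic variables: abundance cutoff -> zeros to missing ->
prevalence filter (>= 30% of all samples by default) -> CLR -> centre and
scale.  Meta-variables are centred and scaled only.  Pearson r with a
two-sided t-test p-value is computed on pairwise-complete observations,
and BH correction runs across all pairs computed in the invocation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .compare import apply_abundance_cutoff, zeros_to_missing
from .io import MappingTable, RelAbundanceTable
from .stats import bh_adjust


@dataclass
class CorrelationConfig:
    abundance_cutoff: float = 0.5  # percent; values below become missing
    prevalence_min: float = 0.30  # fraction of ALL samples a taxon must reach
    pseudocount: float | None = None  # None = detected-taxa-only CLR
    min_n_for_p: int = 3


def clr_transform(values: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Centred log-ratio per sample (columns), over detected taxa only.

    ``values`` is taxa x samples with missing entries for undetected taxa.
    Detected proportions are re-closed to sum to 1 before the transform, so
    each sample's CLR values sum to zero over its detected taxa.  With a
    pseudocount, missing entries are filled before the transform instead.
    """
    out = values.astype(float).copy()
    if pseudocount is not None:
        out = out.fillna(pseudocount)
    dropped = []
    for sample in out.columns:
        col = out[sample]
        detected = col.dropna()
        if len(detected) == 0 or (detected <= 0).any():
            dropped.append(sample)
            continue
        p = detected / detected.sum()
        logp = np.log(p)
        out.loc[detected.index, sample] = logp - logp.mean()
    if dropped:
        warnings.warn(f"samples with no detected taxa dropped: {dropped}", stacklevel=2)
        out = out.drop(columns=dropped)
    return out


def center_scale(values: pd.DataFrame) -> pd.DataFrame:
    """Standardize each variable (row): subtract mean, divide by sd (n-1).

    Statistics use non-missing values only; zero-variance variables are
    dropped with a warning.
    """
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    flat = values.index[(sd == 0) | sd.isna()]
    if len(flat):
        warnings.warn(f"zero-variance variables dropped: {list(flat)}", stacklevel=2)
    kept = values.drop(index=flat)
    return kept.sub(mean[kept.index], axis=0).div(sd[kept.index], axis=0)


def pearson_with_p(x, y, min_n_for_p: int = 3) -> tuple[float, float, int]:
    """Pearson r, two-sided t-test p and n on pairwise-complete observations.

    p = 2 P(T_{n-2} >= |t|) with t = r sqrt((n-2)/(1-r^2)); |r| = 1 gives
    p = 0.  Below ``min_n_for_p`` complete pairs the p-value is missing;
    below 2 the correlation itself is missing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 2:
        return np.nan, np.nan, n
    xv, yv = x[mask], y[mask]
    if np.std(xv) == 0 or np.std(yv) == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xv, yv)[0, 1])
    r = max(-1.0, min(1.0, r))
    if n < min_n_for_p:
        return r, np.nan, n
    if abs(r) >= 1.0 - 1e-15:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return r, float(p), n


def prepare_taxa(rel: RelAbundanceTable, config: CorrelationConfig) -> pd.DataFrame:
    """Taxa pipeline: cutoff -> missing -> prevalence filter -> CLR -> scale."""
    cut = apply_abundance_cutoff(rel, config.abundance_cutoff)
    masked = zeros_to_missing(cut.values)
    n_samples = masked.shape[1]
    # boundary inclusive: detection in 9 of 30 samples meets the 30% default
    frac = masked.notna().sum(axis=1) / n_samples
    kept = masked.loc[frac >= config.prevalence_min]
    clr = clr_transform(kept, pseudocount=config.pseudocount)
    return center_scale(clr)


def correlation_analysis(
    mapping: MappingTable,
    taxa: RelAbundanceTable,
    mode: str = "meta_vs_taxa",
    config: CorrelationConfig | None = None,
) -> pd.DataFrame:
    """Pearson correlations for every variable pair requested by ``mode``.

    Modes: ``meta_vs_taxa`` (default), ``within_meta``, ``within_taxa``,
    ``all``.  Returns one record per pair with r, raw p, BH-adjusted p (one
    family across all pairs in the run) and the number of supporting
    observations.
    """
    config = config or CorrelationConfig()
    if mode not in {"meta_vs_taxa", "within_meta", "within_taxa", "all"}:
        raise ValueError(f"unknown mode {mode!r}")
    common = [s for s in taxa.sample_ids if s in mapping.data.index]
    taxa_common = RelAbundanceTable(values=taxa.values[common], taxonomy=taxa.taxonomy)
    tax_mat = prepare_taxa(taxa_common, config)
    meta_raw = mapping.data.loc[common, mapping.meta_columns].T.astype(float)
    meta_mat = center_scale(meta_raw) if len(meta_raw) else meta_raw

    pairs = []
    if mode in {"meta_vs_taxa", "all"}:
        pairs += [
            (m, "meta", t, "taxonomic")
            for m in meta_mat.index
            for t in tax_mat.index
        ]
    if mode in {"within_meta", "all"}:
        ms = list(meta_mat.index)
        pairs += [
            (ms[i], "meta", ms[j], "meta")
            for i in range(len(ms))
            for j in range(i + 1, len(ms))
        ]
    if mode in {"within_taxa", "all"}:
        ts = list(tax_mat.index)
        pairs += [
            (ts[i], "taxonomic", ts[j], "taxonomic")
            for i in range(len(ts))
            for j in range(i + 1, len(ts))
        ]

    def row_of(var, cls):
        mat = meta_mat if cls == "meta" else tax_mat
        # reindex: CLR may have dropped samples with no detected taxa
        return mat.loc[var].reindex(common).to_numpy(dtype=float)

    rows = []
    for vx, cx, vy, cy in pairs:
        r, p, n = pearson_with_p(row_of(vx, cx), row_of(vy, cy), config.min_n_for_p)
        rows.append(dict(var_x=vx, class_x=cx, var_y=vy, class_y=cy,
                         r=r, p=p, n_obs=n))
    records = pd.DataFrame(
        rows, columns=["var_x", "class_x", "var_y", "class_y", "r", "p", "n_obs"]
    )
    records["p_adj"] = bh_adjust(records["p"].to_numpy()) if len(records) else np.nan
    return records
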