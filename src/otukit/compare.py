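"""Serial group comparisons with the prevalence/abundance filter cascade.

The pipeline for relative-abundance variables is:

1. near-zero zeroing — relative abundances below an abundance cutoff
   (default 0.5%) are set to 0, because taxa that shallow appear and
   disappear essentially at random between technical replicates;
2. zeros become missing — a zero read count is a detection-limit censoring,
   not evidence of absence, so zeros are excluded from all statistics;
3. prevalence gate — a variable is tested only if at least one group has it
   detected in more than ``prevalence_min`` (default 30%) of its samples;
4. median gate — and only if at least one group's median relative abundance
   over detected samples exceeds ``median_min`` (default 1%);
5. Kruskal-Wallis across groups, pairwise Mann-Whitney when more than two
   groups, an exact prevalence (Fisher) test on detection patterns, and
   Benjamini-Hochberg adjustment within each test family.

Alpha-diversity values and numeric meta-variables can ride through the same
testing machinery, but the gates and the zero-masking apply only to
relative-abundance variables — a measured zero in a meta-variable is a real
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MappingTable, RelAbundanceTable, RunLog
from .stats import bh_adjust, fisher_prevalence, kruskal_wallis, mann_whitney


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade.

    abundance_cutoff: percent below which a value is treated as absent
        (strictly below; a value equal to the cutoff is kept).
    prevalence_min: fraction of a group's samples that must be positive in
        at least one group (strictly above; 3/10 fails the default 0.30,
        4/10 passes).
    median_min: percent that at least one group median must strictly exceed.
    """

    abundance_cutoff: float = 0.5
    prevalence_min: float = 0.30
    median_min: float = 1.0

    def __post_init__(self) -> None:
        if self.abundance_cutoff < 0 or self.median_min < 0:
            raise ValueError("cutoffs must be >= 0")
        if not 0 <= self.prevalence_min <= 1:
            raise ValueError("prevalence_min must be a fraction in [0, 1]")


def apply_abundance_cutoff(rel: RelAbundanceTable, cutoff: float) -> RelAbundanceTable:
    """Zero every relative abundance strictly below ``cutoff`` percent."""
    values = rel.values.where(rel.values >= cutoff, 0.0)
    return RelAbundanceTable(values=values, taxonomy=rel.taxonomy)


def zeros_to_missing(values: pd.DataFrame) -> pd.DataFrame:
    """Replace exact zeros by NaN so statistics see only detected values."""
    return values.where(values != 0.0, np.nan)


def group_prevalence(values: pd.DataFrame, groups: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    """Per-group counts of non-missing values, and group sizes.

    Returns (prevalence, sizes): prevalence is variables x groups with the
    number of detected samples, sizes the sample count per group.
    """
    detected = values.notna()
    labels = pd.unique(groups)
    prev = pd.DataFrame(index=values.index, columns=labels, dtype=int)
    sizes = pd.Series(index=labels, dtype=int)
    for g in labels:
        cols = groups.index[groups == g]
        prev[g] = detected[cols].sum(axis=1)
        sizes[g] = len(cols)
    return prev, sizes


def prevalence_gate(
    values: pd.DataFrame, groups: pd.Series, prevalence_min: float
) -> tuple[list, list, pd.DataFrame]:
    """Partition variables into tested/skipped by the prevalence rule.

    Tested iff some group has detected/size strictly greater than
    ``prevalence_min``.
    """
    prev, sizes = group_prevalence(values, groups)
    frac = prev / sizes
    tested_mask = (frac > prevalence_min).any(axis=1)
    tested = list(values.index[tested_mask])
    skipped = list(values.index[~tested_mask])
    return tested, skipped, prev


def median_gate(
    values: pd.DataFrame, groups: pd.Series, median_min: float
) -> tuple[list, list, pd.DataFrame]:
    """Partition variables by the group-median rule.

    Tested iff some group's median over non-missing values strictly exceeds
    ``median_min``.
    """
    labels = pd.unique(groups)
    medians = pd.DataFrame(index=values.index, columns=labels, dtype=float)
    for g in labels:
        cols = groups.index[groups == g]
        medians[g] = values[cols].median(axis=1)
    tested_mask = (medians > median_min).any(axis=1)
    return list(values.index[tested_mask]), list(values.index[~tested_mask]), medians


@dataclass
class ComparisonResults:
    """Output of a serial comparison run."""

    records: pd.DataFrame  # one row per variable
    pairwise: pd.DataFrame  # one row per (variable, group pair)
    group_labels: list
    config: FilterConfig
    log: RunLog = field(default_factory=RunLog)


def _test_variables(values: pd.DataFrame, groups: pd.Series, gated: bool,
                    config: FilterConfig, seed: int):
    """Run the cascade + tests on a variables-x-samples value frame."""
    labels = list(pd.unique(groups))
    records: dict = {}
    skip_reason: dict = {}

    if gated:
        tested_p, skipped_p, prev = prevalence_gate(values, groups, config.prevalence_min)
        for v in skipped_p:
            skip_reason[v] = "prevalence"
        sub = values.loc[tested_p]
        tested_m, skipped_m, medians_all = median_gate(sub, groups, config.median_min)
        for v in skipped_m:
            skip_reason[v] = "median"
        tested = tested_m
    else:
        prev, _ = group_prevalence(values, groups)
        tested = list(values.index)

    _, sizes = group_prevalence(values, groups)
    medians = pd.DataFrame(index=values.index, columns=labels, dtype=float)
    for g in labels:
        cols = groups.index[groups == g]
        medians[g] = values[cols].median(axis=1)

    kw_p, fisher_p = {}, {}
    pairwise_rows = []
    rng = np.random.default_rng(seed)
    for v in tested:
        per_group = [values.loc[v, groups.index[groups == g]].to_numpy(dtype=float)
                     for g in labels]
        nonempty = [g for g, arr in zip(labels, per_group)
                    if np.isfinite(arr).sum() > 0]
        if len(nonempty) < 2:
            skip_reason[v] = "groups"
            continue
        arrays = {g: arr[np.isfinite(arr)] for g, arr in zip(labels, per_group)}
        _, kw_p[v] = kruskal_wallis([arrays[g] for g in nonempty])
        fisher_p[v] = fisher_prevalence(
            [int(prev.loc[v, g]) for g in labels],
            [int(sizes[g]) for g in labels],
            seed=int(rng.integers(2**31)),
        ).p
        for i in range(len(nonempty)):
            for j in range(i + 1, len(nonempty)):
                a, b = nonempty[i], nonempty[j]
                try:
                    u, p = mann_whitney(arrays[a], arrays[b])
                except ValueError:
                    continue
                pairwise_rows.append(dict(variable=v, group_a=a, group_b=b, U=u, p=p))

    rows = []
    for v in values.index:
        row = dict(variable=v, tested=v in kw_p,
                   skip_reason=skip_reason.get(v, ""))
        for g in labels:
            row[f"median_{g}"] = medians.loc[v, g]
            row[f"prevalence_{g}"] = f"{int(prev.loc[v, g])}/{int(sizes[g])}"
        row["kw_p"] = kw_p.get(v, np.nan)
        row["fisher_p"] = fisher_p.get(v, np.nan)
        rows.append(row)
    records_df = pd.DataFrame(rows).set_index("variable")
    records_df["kw_p_adj"] = bh_adjust(records_df["kw_p"].to_numpy())
    records_df["fisher_p_adj"] = bh_adjust(records_df["fisher_p"].to_numpy())

    pw = pd.DataFrame(pairwise_rows, columns=["variable", "group_a", "group_b", "U", "p"])
    if len(pw):
        pw["p_adj"] = bh_adjust(pw["p"].to_numpy())  # pooled across variables x pairs
    else:
        pw["p_adj"] = pd.Series(dtype=float)
    return records_df, pw


def serial_comparison(
    rel: RelAbundanceTable,
    mapping: MappingTable,
    group_col: str,
    config: FilterConfig | None = None,
    meta: pd.DataFrame | None = None,
    seed: int = 0,
) -> ComparisonResults:
    """Systematic testing of every taxonomic variable between sample groups.

    ``rel`` holds relative-abundance variables (rows) per sample (columns);
    the full cascade (cutoff, zero-masking, prevalence and median gates)
    applies to them.  ``meta`` may carry extra variables (alpha-diversity,
    physico-chemical measurements; rows = variables) that are tested as-is,
    without gates or zero-masking.

    BH correction runs within each test family: Kruskal-Wallis p-values
    across variables, Mann-Whitney p-values pooled across all variable-pair
    tests, and Fisher prevalence p-values across variables.
    """
    config = config or FilterConfig()
    log = RunLog()
    groups = mapping.data[group_col].dropna()
    common = [s for s in rel.sample_ids if s in groups.index]
    groups = groups.loc[common].astype(str)
    log.record(group_col=group_col, n_samples=len(common),
               abundance_cutoff=config.abundance_cutoff,
               prevalence_min=config.prevalence_min,
               median_min=config.median_min, seed=seed)

    cut = apply_abundance_cutoff(
        RelAbundanceTable(values=rel.values[common], taxonomy=rel.taxonomy),
        config.abundance_cutoff,
    )
    masked = zeros_to_missing(cut.values)
    records, pairwise = _test_variables(masked, groups, gated=True, config=config,
                                        seed=seed)
    records.insert(0, "class", "taxonomic")

    if meta is not None and len(meta):
        meta_vals = meta[ [c for c in common if c in meta.columns] ]
        m_records, m_pairwise = _test_variables(meta_vals, groups.loc[meta_vals.columns],
                                                gated=False, config=config, seed=seed + 1)
        m_records.insert(0, "class", "meta")
        records = pd.concat([records, m_records])
        pairwise = pd.concat([pairwise, m_pairwise], ignore_index=True)

    labels = list(pd.unique(groups))
    if not records["tested"].any():
        log.record(note="no variable passed the filter cascade")
    return ComparisonResults(records=records, pairwise=pairwise,
                             group_labels=labels, config=config, log=log)
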