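"""Reading, writing and validation of OTU tables, mapping files and trees.

The on-disk dialect is the IMNGS/Rhea-style OTU table: tab-separated, one
row per OTU, first column the OTU identifier, intermediate columns integer
read counts per sample, and a final column named ``taxonomy`` holding a
semicolon-delimited lineage (kingdom → genus/species; empty fields mark
unknown ranks).  Orientation is fixed — no transposition auto-detection is
attempted, since a silently transposed table is a classic corruption source.

Missing values are written and read as ``NA``.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

NA_TOKEN = "NA"

#: number of taxonomic ranks carried per OTU (kingdom..genus)
N_RANKS = 6
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """Raised when an input file violates the format contract."""


def _check_unique(ids, what: str) -> None:
    seen: set = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


def split_lineage(lineage: str) -> list[str]:
    """Split a semicolon-delimited lineage into whitespace-trimmed labels.

    Empty fields (unknown ranks) become empty strings; a trailing semicolon
    does not create an extra rank beyond what the delimiter count implies.
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    # "Bacteria;Firmicutes;;;" splits into 5 fields, the last empty ones
    # being unknown ranks; drop a single trailing empty field only when the
    # string ends with ";" *and* all of it would otherwise be ambiguous --
    # Rhea-style tables pad with semicolons, so we keep every field.
    return parts


@dataclass
class CountTable:
    """Integer read counts, OTUs x samples, with per-OTU taxonomy.

    ``counts`` is a DataFrame indexed by OTU id with one column per sample;
    ``taxonomy`` maps each OTU id to its lineage labels (unknown ranks are
    empty strings).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series  # index = otu ids, values = list[str]

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "OTU")
        _check_unique(self.counts.columns, "sample")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at OTU {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        missing_tax = [o for o in self.counts.index if o not in self.taxonomy.index]
        if missing_tax:
            raise ValidationError(f"OTUs without taxonomy entry: {missing_tax}")

    @property
    def otu_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class NormalizedTable:
    """Real-valued counts after depth normalization.

    Every sample column sums to ``min_depth``, the smallest original
    library size.
    """

    values: pd.DataFrame
    taxonomy: pd.Series
    min_depth: float

    @property
    def otu_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class RelAbundanceTable:
    """Relative abundances in percent; each sample column sums to 100."""

    values: pd.DataFrame
    taxonomy: pd.Series | None = None

    @property
    def otu_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class MappingTable:
    """Per-sample metadata: categorical group columns and numeric meta columns."""

    data: pd.DataFrame  # index = sample ids
    group_columns: list[str]
    meta_columns: list[str]

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        for col in self.group_columns:
            if self.data[col].dropna().empty:
                raise ValidationError(f"group column {col!r} has no non-missing level")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)


@dataclass
class RunLog:
    """Record of every parameter/threshold and input used in a run.

    Written alongside the outputs of each pipeline invocation so any result
    can be traced back to the exact selections that produced it.
    """

    entries: list[str] = field(default_factory=list)

    def record(self, **params) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        for key, value in params.items():
            self.entries.append(f"{stamp}\t{key}\t{value}")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.entries) + "\n")


def read_otu_table(path) -> CountTable:
    """Read a tab-separated OTU table (rows = OTUs, last column = taxonomy)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample")  # pandas would silently mangle dupes
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2 or df.columns[-1].strip().lower() != "taxonomy":
        raise ValidationError(
            "last column must be named 'taxonomy' (semicolon-delimited lineages)"
        )
    otu_col = df.columns[0]
    sample_cols = list(df.columns[1:-1])
    _check_unique(sample_cols, "sample")
    otu_ids = df[otu_col].tolist()
    _check_unique(otu_ids, "OTU")

    counts = pd.DataFrame(index=otu_ids, columns=sample_cols, dtype=float)
    for col in sample_cols:
        try:
            numeric = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric count in column {col!r}: {exc}") from exc
        counts[col] = numeric.to_numpy()
    arr = counts.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValidationError(
            f"non-integral count at OTU {otu_ids[i]!r}, sample {sample_cols[j]!r}"
        )
    counts = counts.astype(np.int64)

    taxonomy = pd.Series(
        [split_lineage(t) for t in df.iloc[:, -1]], index=otu_ids, dtype=object
    )
    return CountTable(counts=counts, taxonomy=taxonomy)


def read_mapping(path, group_cols=(), meta_cols=()) -> MappingTable:
    """Read a tab-separated mapping file (first column = sample id)."""
    df = pd.read_csv(
        path, sep="\t", header=0, index_col=0, na_values=[NA_TOKEN], keep_default_na=False
    )
    for col in list(group_cols) + list(meta_cols):
        if col not in df.columns:
            raise ValidationError(f"declared column {col!r} absent from mapping file")
    for col in meta_cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            cell = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"meta column {col!r} has non-numeric value at sample {cell!r}"
            ) from None
    for col in group_cols:
        df[col] = df[col].astype("category")
    return MappingTable(data=df, group_columns=list(group_cols), meta_columns=list(meta_cols))


def align_samples(table: CountTable, mapping: MappingTable) -> tuple[CountTable, MappingTable]:
    """Restrict both inputs to their common sample set, warning on asymmetry."""
    t_set, m_set = set(table.sample_ids), set(mapping.sample_ids)
    only_t, only_m = sorted(t_set - m_set), sorted(m_set - t_set)
    if only_t or only_m:
        warnings.warn(
            f"sample sets differ: only in OTU table {only_t}, only in mapping {only_m}; "
            "joint analyses use the intersection",
            stacklevel=2,
        )
    common = [s for s in table.sample_ids if s in m_set]
    new_table = CountTable(counts=table.counts[common], taxonomy=table.taxonomy)
    new_map = MappingTable(
        data=mapping.data.loc[common],
        group_columns=mapping.group_columns,
        meta_columns=mapping.meta_columns,
    )
    return new_table, new_map


def read_tree(path, otu_ids=None, prune_extra: bool = False, log: RunLog | None = None):
    """Read a Newick tree; root unrooted input at its midpoint.

    When ``otu_ids`` is given the leaf set is reconciled against the OTU
    table: leaves absent from the table are a hard error unless
    ``prune_extra`` removes them (logged); table OTUs missing from the tree
    are always a hard error, because silently dropping them biases UniFrac.
    """
    tree = skbio.TreeNode.read(str(path), convert_underscores=False)
    children = tree.children
    if len(children) > 2:  # unrooted (basal trifurcation): midpoint-root
        tree = tree.root_at_midpoint()
        if log is not None:
            log.record(tree_rooting="midpoint (input was unrooted)")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    if otu_ids is not None:
        leaf_names = {leaf.name for leaf in tree.tips()}
        _check_unique([leaf.name for leaf in tree.tips()], "leaf")
        missing = sorted(set(otu_ids) - leaf_names)
        if missing:
            raise ValidationError(f"missing leaves (OTUs absent from tree): {missing}")
        extra = sorted(leaf_names - set(otu_ids))
        if extra:
            if not prune_extra:
                raise ValidationError(
                    f"tree leaves absent from OTU table: {extra} "
                    "(pass prune_extra=True to drop them)"
                )
            tree = tree.shear(set(otu_ids))
            tree.prune()
            if log is not None:
                log.record(pruned_leaves=",".join(extra))
    return tree


def _format_value(v) -> str:
    if not isinstance(v, str) and pd.isna(v):
        return NA_TOKEN
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return format(float(v), ".12g")
    return str(v)


def write_table(df: pd.DataFrame, path, index_label: str = "#ID") -> None:
    """Write a DataFrame tab-separated, >= 10 significant digits, NA for missing."""
    out = df.copy()
    for col in out.columns:
        out[col] = [_format_value(v) for v in out[col]]
    out.to_csv(path, sep="\t", index_label=index_label)


def write_matrix(dm: skbio.DistanceMatrix, path) -> None:
    """Write a square distance matrix, tab-separated, full precision."""
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    write_table(df, path, index_label="")


def write_count_table(table: CountTable, path) -> None:
    """Write a CountTable back to the OTU-table dialect (taxonomy last)."""
    df = table.counts.copy()
    df["taxonomy"] = [";".join(table.taxonomy[o]) for o in table.counts.index]
    df.to_csv(path, sep="\t", index_label="#OTUId")


def read_matrix(path) -> skbio.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return skbio.DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])
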