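import io as _io

import numpy as np
import pandas as pd
import pytest
import skbio

from otukit.io import CountTable, MappingTable, NormalizedTable, RelAbundanceTable


@pytest.fixture
def three_leaf_tree():
    return skbio.TreeNode.read(_io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def small_count_table():
    counts = pd.DataFrame(
        {"s1": [10, 90, 0], "s2": [5, 15, 0]},
        index=["OTU_1", "OTU_2", "OTU_3"],
    )
    taxonomy = pd.Series(
        {
            "OTU_1": ["Bacteria", "Firmicutes", "Clostridia", "", "", ""],
            "OTU_2": ["Bacteria", "Bacteroidetes", "", "", "", ""],
            "OTU_3": ["Bacteria", "", "", "", "", ""],
        }
    )
    return CountTable(counts=counts, taxonomy=taxonomy)


@pytest.fixture
def otu_table_file(tmp_path):
    path = tmp_path / "otus.tab"
    path.write_text(
        "#OTUId\tsampleA\tsampleB\ttaxonomy\n"
        "OTU_1\t10\t5\tBacteria;Firmicutes;Clostridia;;;\n"
        "OTU_2\t90\t15\tBacteria;Bacteroidetes;;;;\n"
        "OTU_3\t0\t0\tBacteria;Firmicutes;;;\n"
    )
    return path


@pytest.fixture
def mapping_file(tmp_path):
    path = tmp_path / "mapping.tab"
    path.write_text(
        "#SampleID\tDiet\tFacility\tWeight\n"
        "sampleA\tCD\tSPF\t21.5\n"
        "sampleB\tHFD\tSPF\tNA\n"
    )
    return path


def make_normalized(values: dict, index=None) -> NormalizedTable:
    df = pd.DataFrame(values, index=index, dtype=float)
    tax = pd.Series({i: ["Bacteria"] for i in df.index})
    return NormalizedTable(values=df, taxonomy=tax, min_depth=float(df.sum(axis=0).min()))


def make_rel(values: dict, index=None, taxonomy=None) -> RelAbundanceTable:
    df = pd.DataFrame(values, index=index, dtype=float)
    if taxonomy is None:
        taxonomy = pd.Series({i: ["Bacteria"] for i in df.index})
    return RelAbundanceTable(values=df, taxonomy=taxonomy)


def make_mapping(groups: dict, group_col: str = "Group", meta: dict | None = None):
    df = pd.DataFrame({group_col: pd.Series(groups)})
    meta_cols = []
    if meta:
        for name, vals in meta.items():
            df[name] = pd.Series(vals)
            meta_cols.append(name)
    return MappingTable(data=df, group_columns=[group_col], meta_columns=meta_cols)


def random_distance_matrix(rng: np.random.Generator, n: int) -> skbio.DistanceMatrix:
    pts = rng.standard_normal((n, 4))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return skbio.DistanceMatrix(d, ids=[f"S{i}" for i in range(n)])
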