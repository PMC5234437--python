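"""Synthetic 16S amplicon datasets with the statistical structure the
pipeline assumes.

The generator emulates the two kinds of template data the pipeline is
built around: a grouped study (mouse-gut-like OTU table with a mapping
file and a phylogenetic tree) and a technical-replicate series (repeated
libraries of one faecal sample).  Counts follow a Dirichlet-multinomial:
each sample's composition is drawn from a Dirichlet around a heavy-tailed
base composition (group-specific fold-changes applied to designated effect
OTUs, then re-closed), and reads are multinomial draws at a negative-
binomially distributed depth.  The tree is a pure-birth (Yule) process
with branch lengths scaled to mean root-to-tip depth 1; taxonomy is
derived by cutting the tree at fixed heights, so tree and taxonomy agree
by construction.

Everything is driven by one numpy Generator, so a fixed seed reproduces a
dataset bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .io import CountTable, MappingTable

#: fraction of the tree height at which each rank below kingdom is cut
RANK_CUT_FRACTIONS = {"phylum": 0.15, "class": 0.35, "order": 0.55,
                      "family": 0.70, "genus": 0.85}
RANK_PREFIX = {"phylum": "p", "class": "c", "order": "o", "family": "f", "genus": "g"}


@dataclass
class SimConfig:
    """Study conditions for the grouped-dataset generator.

    Defaults mirror a typical small animal study profiled at MiSeq depth:
    two groups of 10 samples, 100 OTUs, ~20,000 reads per library with
    moderate library-size spread, and Dirichlet concentration 50 (clear
    between-mouse compositional variation).  ``effects`` lists
    (otu_id, group_label, fold_change) triples applied to the base
    composition of that group.
    """

    n_samples: int = 10  # per group
    n_groups: int = 2
    n_otus: int = 100
    depth_mean: float = 20_000.0
    depth_dispersion: float = 20.0  # negative-binomial size; larger = tighter
    concentration: float = 50.0  # Dirichlet concentration around the base
    base_log_sd: float = 1.5  # log-normal spread of base OTU abundances
    base_proportions: tuple | None = None  # explicit base composition override
    effects: list[tuple] = field(default_factory=list)
    birth_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_groups, self.n_otus) < 1:
            raise ValueError("sample, group and OTU counts must be positive")
        if self.depth_mean <= 0 or self.concentration <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth and concentration parameters must be positive")
        for eff in self.effects:
            if len(eff) != 3 or eff[2] <= 0:
                raise ValueError(f"effect must be (otu, group, fold>0): {eff!r}")


def yule_tree(n_tips: int, rng: np.random.Generator, birth_rate: float = 1.0):
    """Ultrametric pure-birth tree with tips OTU_1..OTU_n, mean depth 1."""
    names = [f"OTU_{i + 1}" for i in range(n_tips)]
    root = skbio.TreeNode()
    start = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.length = t - start[id(node)]
        for _ in range(2):
            child = skbio.TreeNode()
            start[id(child)] = t
            node.append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * max(len(active), 1)))
    order = rng.permutation(len(active))
    for name_i, node_i in enumerate(order):
        active[node_i].name = names[name_i]
        active[node_i].length = t_end - start[id(active[node_i])]
    if n_tips == 1:
        root.name = names[0]
        root.length = None
        return root
    root.length = None
    # scale to root-to-tip depth exactly 1 (tree is ultrametric)
    height = 0.0
    node = active[0]
    while node.parent is not None:
        height += node.length
        node = node.parent
    if height > 0:
        for node in root.traverse(include_self=False):
            node.length = node.length / height
    return root


def taxonomy_from_tree(tree) -> pd.Series:
    """Six-rank lineages obtained by cutting the tree at fixed heights.

    All tips share kingdom ``Bacteria``; at each deeper rank, tips cluster
    by the branch their root-to-tip path crosses at that height, so the
    taxonomy is consistent with the tree by construction.
    """
    depth_of = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depth_of[id(node)] = depth_of[id(node.parent)] + (node.length or 0.0)
    tips = list(tree.tips())
    height = max(depth_of[id(t)] for t in tips) if tips else 1.0
    lineages: dict[str, list[str]] = {t.name: ["Bacteria"] for t in tips}
    for rank, frac in RANK_CUT_FRACTIONS.items():
        h = frac * height
        clusters: dict[int, int] = {}
        for tip in tips:
            node = tip
            crossing = tip
            while node.parent is not None:
                if depth_of[id(node.parent)] <= h:
                    crossing = node
                    break
                node = node.parent
            clusters.setdefault(id(crossing), len(clusters) + 1)
            lineages[tip.name].append(
                f"{RANK_PREFIX[rank]}_{clusters[id(crossing)]:02d}"
            )
    return pd.Series({name: lineages[name] for name in (t.name for t in tips)})


def _base_composition(config: SimConfig, rng) -> np.ndarray:
    if config.base_proportions is not None:
        base = np.asarray(config.base_proportions, dtype=float)
        if len(base) != config.n_otus or (base <= 0).any():
            raise ValueError("base_proportions must be positive, one per OTU")
        return base / base.sum()
    raw = np.exp(rng.normal(0.0, config.base_log_sd, size=config.n_otus))
    return raw / raw.sum()


def simulate_dataset(config: SimConfig):
    """Grouped OTU table + mapping + tree + true-effect record.

    Returns (CountTable, MappingTable, tree, truth) where truth is a
    DataFrame of the planted (otu, group, fold_change) effects.
    """
    rng = np.random.default_rng(config.seed)
    tree = yule_tree(config.n_otus, rng, config.birth_rate)
    taxonomy = taxonomy_from_tree(tree)
    otu_ids = [f"OTU_{i + 1}" for i in range(config.n_otus)]
    base = _base_composition(config, rng)

    group_labels = [f"G{g + 1}" for g in range(config.n_groups)]
    group_means = {}
    for g in group_labels:
        mean = base.copy()
        for otu, grp, fold in config.effects:
            if str(grp) == g:
                mean[otu_ids.index(otu)] *= fold
        group_means[g] = mean / mean.sum()

    counts = {}
    rows = []
    for g in group_labels:
        alpha = config.concentration * group_means[g]
        for i in range(config.n_samples):
            sample = f"{g}_S{i + 1}"
            depth = 0
            while depth == 0:
                depth = rng.negative_binomial(
                    config.depth_dispersion,
                    config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
                )
            comp = rng.dirichlet(alpha)
            counts[sample] = rng.multinomial(depth, comp)
            rows.append(dict(sample=sample, Group=g))

    table = CountTable(
        counts=pd.DataFrame(counts, index=otu_ids), taxonomy=taxonomy.loc[otu_ids]
    )
    mapping = MappingTable(
        data=pd.DataFrame(rows).set_index("sample"),
        group_columns=["Group"],
        meta_columns=[],
    )
    truth = pd.DataFrame(config.effects, columns=["otu", "group", "fold_change"])
    return table, mapping, tree, truth


def simulate_replicates(
    config: SimConfig, n_replicates: int = 10, noise: float = 0.0
):
    """Technical-replicate libraries of one sample.

    All replicates share one true composition; ``noise`` > 0 adds
    Dirichlet-multinomial overdispersion (composition redrawn per replicate
    from Dirichlet(comp / noise)); ``noise`` = 0 gives pure multinomial
    resampling.  Emulates repeated library construction + sequencing of a
    single faecal DNA extract.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(config.seed)
    tree = yule_tree(config.n_otus, rng, config.birth_rate)
    taxonomy = taxonomy_from_tree(tree)
    otu_ids = [f"OTU_{i + 1}" for i in range(config.n_otus)]
    truth = _base_composition(config, rng)
    counts = {}
    for r in range(n_replicates):
        depth = 0
        while depth == 0:
            depth = rng.negative_binomial(
                config.depth_dispersion,
                config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
            )
        comp = rng.dirichlet(truth / noise) if noise > 0 else truth
        counts[f"Rep_{r + 1}"] = rng.multinomial(depth, comp)
    return CountTable(
        counts=pd.DataFrame(counts, index=otu_ids), taxonomy=taxonomy.loc[otu_ids]
    )


#: mean-relative-abundance band edges (percent) used to summarize CV
CV_BAND_EDGES = (0.1, 0.5)


def replicate_cv(table: CountTable) -> pd.DataFrame:
    """Per-OTU mean relative abundance (%) and coefficient of variation (%).

    CV = sd / mean x 100 across replicate libraries, computed on per-sample
    percentages; OTUs never observed (mean 0) are excluded (CV undefined).
    Each record carries the abundance band (< 0.1%, 0.1-0.5%, >= 0.5%).
    """
    if table.counts.shape[1] < 2:
        raise ValueError("CV needs at least 2 replicate samples")
    rel = 100.0 * table.counts / table.counts.sum(axis=0)
    mean = rel.mean(axis=1)
    sd = rel.std(axis=1, ddof=1)
    records = pd.DataFrame({"mean_abundance": mean, "cv": 100.0 * sd / mean})
    records = records[records["mean_abundance"] > 0]
    lo, hi = CV_BAND_EDGES
    records["band"] = pd.cut(
        records["mean_abundance"],
        bins=[0, lo, hi, np.inf],
        labels=[f"<{lo}%", f"{lo}-{hi}%", f">={hi}%"],
        right=False,
    )
    return records


def cv_band_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-band OTU count and mean CV (the headline replicate statistics)."""
    return records.groupby("band", observed=False).agg(
        n=("cv", "size"), mean_cv=("cv", "mean")
    )
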