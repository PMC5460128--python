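"""Region-association graphs and ANOVA comparisons of mean ADC.

For one Ki-67 group, the six regions are nodes of an undirected, unweighted
graph; an edge joins two regions when the Pearson correlation of their
per-case mean ADC values is significant after Bonferroni correction over the
15 region pairs (corrected p < 0.05).  Aggressive (high-Ki-67) tumours are
expected to couple non-adjacent regions, giving a denser graph and a higher
total degree than the low-Ki-67 group, whose edges sit mostly between
adjacent regions.

The Bonferroni family is the 15 pairs within one group: the two group graphs
are built and interpreted separately.  Pearson p-values are two-sided from
the exact t transform with n-2 degrees of freedom.  Cases missing a mean for
either region of a pair are dropped pairwise, so each pair uses all cases
with both regions observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sstats

from .segmentation import REGION_NAMES

N_PAIRS = len(REGION_NAMES) * (len(REGION_NAMES) - 1) // 2  # 15
EDGE_ALPHA = 0.05


@dataclass(frozen=True)
class RegionGraph:
    """Per-group correlation graph over the six regions."""

    group: str
    graph: nx.Graph = field(repr=False)
    pair_stats: pd.DataFrame = field(repr=False)  # per pair: r, p_raw, p_bonf, edge, n

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def degrees(self) -> dict[str, int]:
        return {name: int(self.graph.degree[name]) for name in REGION_NAMES}

    @property
    def total_degree(self) -> int:
        return sum(self.degrees.values())


def build_region_graph(feature_table: pd.DataFrame, group: str) -> RegionGraph:
    """Significance-gated Pearson graph of per-case region mean ADC.

    ``group`` selects the "high" or "low" Ki-67 subset of the table.  A pair
    whose usable sample is smaller than 4 cases, or where either region's
    means have zero variance, has an undefined correlation: it is recorded
    with NaN statistics and contributes no edge.
    """
    if group not in ("high", "low"):
        raise ValueError(f"group must be 'high' or 'low', got {group!r}")
    sub = feature_table[feature_table["ki67_label"] == group]
    means = {name: sub[f"mean__{name}"].to_numpy(dtype=float) for name in REGION_NAMES}
    if len(sub) < 4:
        raise ValueError(f"group {group!r} has {len(sub)} cases; need >= 4")

    g = nx.Graph()
    g.add_nodes_from(REGION_NAMES)
    records = []
    for a, b in combinations(REGION_NAMES, 2):
        xa, xb = means[a], means[b]
        keep = ~(np.isnan(xa) | np.isnan(xb))
        n = int(keep.sum())
        r = p_raw = p_bonf = np.nan
        edge = False
        if n >= 4 and np.std(xa[keep]) > 0 and np.std(xb[keep]) > 0:
            res = sstats.pearsonr(xa[keep], xb[keep])
            r, p_raw = float(res.statistic), float(res.pvalue)
            p_bonf = min(1.0, N_PAIRS * p_raw)
            edge = p_bonf < EDGE_ALPHA
        if edge:
            g.add_edge(a, b)
        records.append(
            {
                "region_a": a,
                "region_b": b,
                "n": n,
                "r": r,
                "p_raw": p_raw,
                "p_bonf": p_bonf,
                "edge": edge,
            }
        )
    return RegionGraph(group=group, graph=g, pair_stats=pd.DataFrame(records))


def degree_summary(graph: RegionGraph) -> pd.DataFrame:
    """Per-node degrees plus the total (sum over nodes = 2 x edge count)."""
    rows = [{"region": name, "degree": deg} for name, deg in graph.degrees.items()]
    rows.append({"region": "total", "degree": graph.total_degree})
    return pd.DataFrame(rows)


def one_way_anova(groups: dict[str, np.ndarray]) -> dict[str, float]:
    """One-way ANOVA over named groups of observations.

    Groups with fewer than 2 observations are excluded (with the exclusion
    recorded); NaNs are dropped within each group.  Returns F, p and the
    degrees of freedom actually used.
    """
    used = {}
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if v.size >= 2:
            used[name] = v
    if len(used) < 2:
        raise ValueError("ANOVA needs at least two groups with >= 2 cases")
    f, p = sstats.f_oneway(*used.values())
    n = sum(v.size for v in used.values())
    return {
        "F": float(f),
        "p": float(p),
        "df_between": len(used) - 1,
        "df_within": n - len(used),
        "excluded_groups": sorted(set(groups) - set(used)),
    }


def anova_across_regions(feature_table: pd.DataFrame) -> dict[str, float]:
    """Does mean ADC differ among the six regions? (regions as groups)."""
    groups = {
        name: feature_table[f"mean__{name}"].to_numpy(dtype=float)
        for name in REGION_NAMES
    }
    return one_way_anova(groups)


def anova_between_groups(
    feature_table: pd.DataFrame, column: str = "mean__S_T"
) -> dict[str, float]:
    """Does a feature (default tumour mean ADC) differ by Ki-67 status?"""
    groups = {
        label: feature_table.loc[feature_table["ki67_label"] == label, column]
        .to_numpy(dtype=float)
        for label in ("high", "low")
    }
    return one_way_anova(groups)
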