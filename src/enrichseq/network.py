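"""OTU co-occurrence network with the MENA-style filters and threshold.

Features are first filtered (at most ``max_zeros`` zero samples, total
reads above the ``majority`` floor), counts are log10-transformed with
zeros kept blank (missing), Pearson correlation is computed over
pairwise-complete samples, and an undirected signed edge is emitted for
every pair reaching |r| >= threshold with enough complete pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .io import CountMatrix

DEFAULT_THRESHOLD = 0.7
DEFAULT_MAX_ZEROS = 2
DEFAULT_MAJORITY = 1
DEFAULT_MIN_PAIRS = 9


def filter_features(
    counts: CountMatrix,
    max_zeros: int = DEFAULT_MAX_ZEROS,
    majority: int = DEFAULT_MAJORITY,
) -> CountMatrix:
    """Keep features with <= max_zeros zero samples and total reads > majority."""
    if len(counts.sample_ids) < 3:
        raise ValueError("need at least 3 samples to filter for correlation")
    values = counts.counts
    zeros = (values == 0).sum(axis=1)
    keep = (zeros <= max_zeros) & (values.sum(axis=1) > majority)
    if not keep.any():
        warnings.warn("all features removed by the occurrence/abundance filter")
    return CountMatrix(values.loc[keep].copy(), counts.meta)


@dataclass
class CoNetwork:
    """Signed correlation graph over filtered features."""

    graph: nx.Graph
    params: dict
    skipped_pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature_a": a,
                "feature_b": b,
                "r": d["r"],
                "sign": d["sign"],
                "n_pairs": d["n_pairs"],
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["feature_a", "feature_b", "r", "sign", "n_pairs"]
        )

    def nodes_frame(self) -> pd.DataFrame:
        rows = [{"feature_id": n, **d} for n, d in self.graph.nodes(data=True)]
        return pd.DataFrame(rows)

    def write(self, edges_path, nodes_path=None, graphml_path=None) -> None:
        self.edges_frame().to_csv(edges_path, sep="\t", index=False)
        if nodes_path is not None:
            self.nodes_frame().to_csv(nodes_path, sep="\t", index=False)
        if graphml_path is not None:
            nx.write_graphml(self.graph, str(graphml_path))


def build_network(
    counts: CountMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    taxonomy: pd.DataFrame | None = None,
) -> CoNetwork:
    """Pearson co-occurrence network on log10 counts with zeros as missing.

    Pairs with fewer than ``min_pairs`` jointly-positive samples are skipped
    and recorded rather than tested.  Edges store r, its sign and the number
    of complete pairs; nodes carry lineage columns when a taxonomy is given.
    """
    values = counts.counts.astype(float)
    logged = np.log10(values.where(values > 0))
    r = logged.T.corr(min_periods=min_pairs)
    present = logged.notna().astype(int)
    n_pairs = present @ present.T

    graph = nx.Graph()
    for fid in values.index:
        attrs = {}
        if taxonomy is not None and fid in taxonomy.index:
            attrs = {k: str(v) for k, v in taxonomy.loc[fid].items()}
        graph.add_node(fid, **attrs)

    skipped = []
    for a, b in combinations(values.index, 2):
        n = int(n_pairs.loc[a, b])
        if n < min_pairs:
            skipped.append((a, b, n))
            continue
        rv = r.loc[a, b]
        if pd.notna(rv) and abs(rv) >= threshold:
            graph.add_edge(
                a, b, r=float(rv), sign=1 if rv > 0 else -1, n_pairs=n
            )
    params = {"threshold": threshold, "min_pairs": min_pairs}
    return CoNetwork(graph, params, skipped)


def group_associations(
    network: CoNetwork,
    taxonomy: pd.DataFrame,
    rank: str = "family",
) -> tuple[pd.DataFrame, list[str]]:
    """Signed rank-level association table from the feature network.

    For every pair of rank groups connected by at least one edge: positive
    and negative edge counts and the net sign (majority vote; a tie is
    "mixed").  Returns (association table, groups with no edges at all).
    Nodes without a lineage fall into "unclassified".
    """
    def group_of(node: str) -> str:
        if node in taxonomy.index:
            value = taxonomy.loc[node, rank]
            if pd.notna(value) and str(value):
                return str(value)
        return "unclassified"

    tallies: dict[tuple[str, str], list[int]] = {}
    touched: set[str] = set()
    for a, b, data in network.graph.edges(data=True):
        ga, gb = sorted((group_of(a), group_of(b)))
        pos_neg = tallies.setdefault((ga, gb), [0, 0])
        pos_neg[0 if data["sign"] > 0 else 1] += 1
        touched.update((ga, gb))

    rows = []
    for (ga, gb), (pos, neg) in sorted(tallies.items()):
        if pos > neg:
            net = "positive"
        elif neg > pos:
            net = "negative"
        else:
            net = "mixed"
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_positive": pos,
                "n_negative": neg,
                "net_sign": net,
            }
        )
    table = pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_positive", "n_negative", "net_sign"]
    )
    all_groups = {group_of(n) for n in network.graph.nodes}
    isolated = sorted(all_groups - touched)
    return table, isolated


def permutation_null_edge_rate(
    counts: CountMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    n_permutations: int = 50,
    rng_seed: int = 0,
) -> float:
    """Diagnostic: expected fraction of feature pairs forming an edge when
    each feature's samples are independently permuted (no real structure)."""
    rng = np.random.default_rng(rng_seed)
    values = counts.counts.to_numpy().astype(float)
    n_feat, n_samp = values.shape
    n_possible = n_feat * (n_feat - 1) // 2
    rates = []
    for _ in range(n_permutations):
        perm = np.empty_like(values)
        for i in range(n_feat):
            perm[i] = values[i, rng.permutation(n_samp)]
        cm = CountMatrix(
            pd.DataFrame(perm, index=counts.counts.index, columns=counts.sample_ids)
        )
        net = build_network(cm, threshold=threshold, min_pairs=min_pairs)
        rates.append(net.graph.number_of_edges() / n_possible)
    return float(np.mean(rates))
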