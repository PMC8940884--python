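"""Proportionality-based co-occurrence networks with richness-constrained nulls.

Pairwise association between taxa is measured by the symmetric proportionality
coefficient on centered log-ratio (clr) transformed counts,

    r(x, y) = 2 cov(a_x, a_y) / (var(a_x) + var(a_y)),

which is robust to the constant-sum constraint that distorts Pearson
correlation on compositions. Edges are kept when |r| strictly exceeds a
threshold (default 0.6) after restricting to taxa with more than ``min_total``
reads overall (default 50). Global network significance is assessed by
comparing the observed edge count with edge counts from null count tables that
preserve, per sample, the richness, the total and the multiset of nonzero
values while shuffling which taxa carry them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .io_formats import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "CooccurrenceNetwork",
    "NullEdgeDistribution",
    "filter_taxa",
    "clr_transform",
    "proportionality",
    "build_network",
    "richness_constrained_null",
    "edge_count_test",
    "topology_report",
]


@dataclass
class CooccurrenceNetwork:
    """Thresholded signed proportionality graph over filtered taxa."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (taxon_a, taxon_b, coefficient)
    threshold: float

    def __post_init__(self) -> None:
        for a, b, r in self.edges:
            if a == b:
                raise ValueError("self-edge in network")
            if abs(r) <= self.threshold:
                raise ValueError("edge coefficient does not exceed threshold")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_positive_edges(self) -> int:
        return sum(1 for _, _, r in self.edges if r > 0)

    @property
    def n_negative_edges(self) -> int:
        return self.n_edges - self.n_positive_edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges, weight="coefficient")
        return g

    @property
    def n_connected_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())


@dataclass
class NullEdgeDistribution:
    """Observed edge count vs the null edge-count distribution."""

    observed_edge_count: int
    null_edge_counts: list[int]
    seed: int | None

    @property
    def n_null(self) -> int:
        return len(self.null_edge_counts)

    @property
    def empirical_p(self) -> float:
        exceed = sum(1 for x in self.null_edge_counts if x >= self.observed_edge_count)
        return (1 + exceed) / (1 + self.n_null)


def filter_taxa(table: CountTable, min_total: int = 50) -> CountTable:
    """Keep taxa whose total count is strictly greater than ``min_total``."""
    totals = table.counts.sum(axis=0)
    keep = [t for t, tot in zip(table.taxon_ids, totals) if tot > min_total]
    if not keep:
        logger.warning("filter_taxa removed every taxon (min_total=%d)", min_total)
    return table.select_taxa(keep)


def clr_transform(table: CountTable, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform of counts with a pseudocount; rows sum to 0."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logs = np.log(table.counts.astype(float) + pseudocount)
    return logs - logs.mean(axis=1, keepdims=True)


def proportionality(clr_matrix: np.ndarray) -> np.ndarray:
    """Symmetric proportionality coefficients between taxa (clr columns).

    Taxa with zero variance across samples yield NaN coefficients off the
    diagonal and are reported with a warning; callers should treat NaN as
    "no association measurable".
    """
    clr_matrix = np.asarray(clr_matrix, dtype=float)
    n, t = clr_matrix.shape
    if n < 3:
        raise ValueError("proportionality requires at least 3 samples")
    cov = np.cov(clr_matrix, rowvar=False)
    var = np.diag(cov).copy()
    zero_var = var <= 0
    if zero_var.any():
        logger.warning("%d taxa with zero variance excluded", int(zero_var.sum()))
    denom = var[:, None] + var[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 2.0 * cov / denom
    r[zero_var, :] = np.nan
    r[:, zero_var] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def build_network(
    coefficients: np.ndarray,
    taxon_ids: list[str],
    threshold: float = 0.6,
) -> CooccurrenceNetwork:
    """Edges for every unordered taxon pair with |r| strictly above threshold."""
    coefficients = np.asarray(coefficients, dtype=float)
    t = len(taxon_ids)
    edges = []
    iu = np.triu_indices(t, k=1)
    vals = coefficients[iu]
    hit = np.abs(vals) > threshold
    for i, j, r in zip(iu[0][hit], iu[1][hit], vals[hit]):
        if np.isnan(r):
            continue
        edges.append((taxon_ids[i], taxon_ids[j], float(r)))
    return CooccurrenceNetwork(list(taxon_ids), edges, threshold)


def richness_constrained_null(
    table: CountTable, seed=None
) -> CountTable:
    """One null table preserving per-sample richness, total and value multiset.

    For each sample independently, the observed nonzero count values are
    reassigned to a fresh taxon set of the same size, drawn without replacement
    with probability proportional to each taxon's occurrence frequency in the
    whole table, in random order. Taxon-taxon coupling is destroyed; per-sample
    structure (richness, depth, abundance distribution) is kept exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq = (table.counts > 0).sum(axis=0).astype(float)
    out = np.zeros_like(table.counts)
    pos = np.flatnonzero(freq > 0)
    p = freq[pos] / freq[pos].sum()
    for i in range(table.n_samples):
        values = table.counts[i, table.counts[i] > 0]
        k = values.size
        if k == 0:
            continue
        chosen = rng.choice(pos, size=k, replace=False, p=p)
        out[i, chosen] = rng.permutation(values)
    return CountTable(list(table.sample_ids), list(table.taxon_ids), out)


def _count_edges(
    table: CountTable, threshold: float, pseudocount: float = 1.0
) -> int:
    clr = clr_transform(table, pseudocount)
    r = proportionality(clr)
    iu = np.triu_indices(r.shape[0], k=1)
    vals = r[iu]
    return int(np.sum(np.abs(vals[~np.isnan(vals)]) > threshold))


def edge_count_test(
    table: CountTable,
    n_null: int = 99,
    threshold: float = 0.6,
    min_total: int = 50,
    seed: int | None = None,
    pseudocount: float = 1.0,
) -> NullEdgeDistribution:
    """Global edge-count significance against richness-constrained null tables.

    The observed pipeline is filter → clr → proportionality → threshold →
    count edges; each of the ``n_null`` null tables (drawn from the filtered
    table) runs the identical downstream pipeline.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    filtered = filter_taxa(table, min_total)
    if filtered.n_taxa < 2:
        raise ValueError("fewer than 2 taxa pass the abundance filter")
    observed = _count_edges(filtered, threshold, pseudocount)
    rng = np.random.default_rng(seed)
    null_counts = [
        _count_edges(richness_constrained_null(filtered, rng), threshold, pseudocount)
        for _ in range(n_null)
    ]
    return NullEdgeDistribution(observed, null_counts, seed)


def network_pipeline(
    table: CountTable,
    threshold: float = 0.6,
    min_total: int = 50,
    pseudocount: float = 1.0,
) -> CooccurrenceNetwork:
    """Filter, clr-transform, compute proportionality and threshold the graph."""
    filtered = filter_taxa(table, min_total)
    r = proportionality(clr_transform(filtered, pseudocount))
    return build_network(r, list(filtered.taxon_ids), threshold)


def topology_report(networks: dict[str, CooccurrenceNetwork]) -> pd.DataFrame:
    """Per-network topology summary: nodes, edges, components, edge signs."""
    if not networks:
        raise ValueError("at least one network required")
    rows = []
    for name, net in networks.items():
        rows.append(
            {
                "network": name,
                "nodes": net.n_nodes,
                "edges": net.n_edges,
                "connected_components": net.n_connected_components,
                "positive_edges": net.n_positive_edges,
                "negative_edges": net.n_negative_edges,
            }
        )
    return pd.DataFrame(rows).set_index("network")
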