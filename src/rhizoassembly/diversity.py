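"""Alpha diversity, rarefaction, beta-diversity distances, PCoA, group tests.

Shannon entropy is reported in nats. Weighted UniFrac defaults to the
normalized variant so all three beta-diversity metrics live on [0, 1].
UniFrac computation is delegated to scikit-bio; Bray-Curtis and PCoA are
computed directly from their definitions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy import stats
from statsmodels.stats.multitest import multipletests
from skbio import TreeNode
from skbio.diversity import beta_diversity as _skbio_beta_diversity

from .io_formats import CountTable, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaDiversityRecord",
    "DistanceMatrix",
    "OrdinationResult",
    "alpha_diversity",
    "rarefy",
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pcoa",
    "group_tests",
]


@dataclass
class AlphaDiversityRecord:
    sample_id: str
    observed_richness: int
    shannon: float


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with a zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        self.data = np.clip(d, 0.0, None)

    def __getitem__(self, pair) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.data[i, j])

    def reorder(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    """PCoA output: coordinates for positive-eigenvalue axes only.

    Negative eigenvalues (possible for non-Euclidean dissimilarities) are
    reported as-is; proportion explained is relative to the sum of positive
    eigenvalues.
    """

    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, n_positive_axes)
    eigenvalues: np.ndarray  # all n eigenvalues, decreasing
    proportion_explained: np.ndarray  # per positive axis


def alpha_diversity(table: CountTable) -> list[AlphaDiversityRecord]:
    """Observed richness and Shannon index (nats) per sample."""
    records = []
    for sid, row in zip(table.sample_ids, table.counts):
        present = row[row > 0]
        richness = int(present.size)
        if richness == 0:
            shannon = 0.0
        else:
            p = present / present.sum()
            shannon = float(-(p * np.log(p)).sum())
        records.append(AlphaDiversityRecord(sid, richness, shannon))
    return records


def alpha_table(records: list[AlphaDiversityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.observed_richness, r.shannon) for r in records],
        columns=["sample_id", "observed_richness", "shannon"],
    ).set_index("sample_id")


def rarefy(table: CountTable, depth: int, seed: int | None = None) -> CountTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    kept_ids, rows = [], []
    for sid, row in zip(table.sample_ids, table.counts):
        total = int(row.sum())
        if total < depth:
            logger.warning(
                "dropping sample %s: %d reads < rarefaction depth %d",
                sid, total, depth,
            )
            continue
        rows.append(rng.multivariate_hypergeometric(row, depth, method="marginals"))
        kept_ids.append(sid)
    counts = np.vstack(rows) if rows else np.empty((0, table.n_taxa), dtype=np.int64)
    return CountTable(kept_ids, list(table.taxon_ids), counts)


def _check_no_zero_rows(table: CountTable) -> None:
    sums = table.counts.sum(axis=1)
    if (sums == 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t == 0]
        raise ValueError(f"all-zero samples: {bad}")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y) on raw counts."""
    _check_no_zero_rows(table)
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def _check_tree_coverage(table: CountTable, tree: TreeNode) -> None:
    leaves = {leaf.name for leaf in tree.tips()}
    used = {
        t for t, c in zip(table.taxon_ids, table.counts.sum(axis=0)) if c > 0
    }
    missing = used - leaves
    if missing:
        raise KeyError(f"taxa missing from tree: {sorted(missing)}")


def _unifrac(table: CountTable, tree: TreeNode, metric: str, **kwargs) -> DistanceMatrix:
    _check_no_zero_rows(table)
    _check_tree_coverage(table, tree)
    # restrict to taxa on the tree; absent-everywhere taxa may be off-tree
    leaves = {leaf.name for leaf in tree.tips()}
    keep = [t for t in table.taxon_ids if t in leaves]
    sub = table.select_taxa(keep)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dm = _skbio_beta_diversity(
            metric,
            sub.counts,
            ids=sub.sample_ids,
            taxa=sub.taxon_ids,
            tree=tree,
            validate=False,
            **kwargs,
        )
    return DistanceMatrix(list(table.sample_ids), np.asarray(dm.data))


def unweighted_unifrac(table: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Fraction of branch length unique to either sample's taxa."""
    return _unifrac(table, tree, "unweighted_unifrac")


def weighted_unifrac(
    table: CountTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Abundance-weighted UniFrac; normalized to [0, 1] by default."""
    return _unifrac(table, tree, "weighted_unifrac", normalized=normalized)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -1/2 J D^2 J."""
    a = -0.5 * np.asarray(d, dtype=float) ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis by eigendecomposition of the Gower matrix."""
    n = len(dm.sample_ids)
    if n < 2:
        raise ValueError("PCoA requires at least 2 samples")
    g = gower_center(dm.data)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0])) if n else eigvals > 0
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    return OrdinationResult(list(dm.sample_ids), coords, eigvals, prop)


def group_tests(
    records: list[AlphaDiversityRecord],
    metadata: SampleMetadata,
    factor: str = "sample_type",
    metric: str = "observed_richness",
) -> dict:
    """Kruskal-Wallis across groups plus BH-adjusted pairwise Wilcoxon rank-sum.

    Returns a dict with the omnibus statistic/p and a pairwise DataFrame with
    raw and Benjamini-Hochberg adjusted p-values.
    """
    values = {r.sample_id: getattr(r, metric) for r in records}
    groups: dict[str, list[float]] = {}
    for sid, v in values.items():
        g = str(metadata.records.loc[sid, factor])
        groups.setdefault(g, []).append(v)
    if len(groups) < 2:
        raise ValueError("group_tests requires at least 2 groups")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty group")
    names = sorted(groups)
    kw_stat, kw_p = stats.kruskal(*(groups[g] for g in names))
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = stats.mannwhitneyu(
                groups[names[i]], groups[names[j]], alternative="two-sided"
            )
            rows.append((names[i], names[j], float(res.pvalue)))
    pvals = [r[2] for r in rows]
    adj = multipletests(pvals, method="fdr_bh")[1] if rows else []
    pairwise = pd.DataFrame(
        [(a, b, p, q) for (a, b, p), q in zip(rows, adj)],
        columns=["group_a", "group_b", "p", "p_adj"],
    )
    return {
        "factor": factor,
        "metric": metric,
        "kruskal_statistic": float(kw_stat),
        "kruskal_p": float(kw_p),
        "pairwise": pairwise,
    }
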