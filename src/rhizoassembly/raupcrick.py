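"""Modified Raup-Crick dissimilarity (βRC) under richness-constrained nulls.

For each sample pair, βRC is the probability that two null communities —
drawn at the pair's observed richnesses by sampling taxa without replacement
with probability proportional to their occurrence frequency in the constraint
group — share at least as many taxa as observed, with ties split:

    βRC = [ #(J_null > J_obs) + 1/2 #(J_null = J_obs) ] / n_simulations

βRC near 0 means the pair shares more taxa than chance (stochastic assembly
from a common pool), near 1 more different than chance (deterministic or
historically contingent divergence), near 0.5 null-consistent.

Null models are constrained within each sample group; pairs that straddle two
groups are evaluated against occurrence frequencies pooled over the union of
the two groups, the only scope that defines a common pool for the pair.

Weighted sampling without replacement uses the Gumbel top-k construction,
equivalent to drawing taxa one at a time with probability proportional to
weight (the scheme behind R's ``sample(prob=)``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import CountTable, SampleMetadata

__all__ = [
    "NullConfig",
    "BetaRCResult",
    "occurrence_frequencies",
    "null_community",
    "beta_rc_pair",
    "beta_rc",
    "analytic_rc_equal_freq",
]


@dataclass(frozen=True)
class NullConfig:
    """Configuration of the richness-constrained null model."""

    n_simulations: int = 999
    constraint: Sequence[str] = ("sample_type",)
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")


@dataclass
class BetaRCResult:
    """Pairwise βRC probabilities plus the null configuration that made them."""

    sample_ids: list[str]
    data: np.ndarray
    groups: list[str]
    n_simulations: int
    seed: int | None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if (d < 0).any() or (d > 1).any():
            raise ValueError("βRC entries must lie in [0, 1]")
        self.data = d

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)

    def group_mean(self, group_a: str, group_b: str) -> float:
        """Mean βRC over pairs with one sample in each group (off-diagonal)."""
        ga = np.array([g == group_a for g in self.groups])
        gb = np.array([g == group_b for g in self.groups])
        if not ga.any() or not gb.any():
            raise ValueError("empty group in group_mean")
        vals = []
        idx_a, idx_b = np.flatnonzero(ga), np.flatnonzero(gb)
        for i in idx_a:
            for j in idx_b:
                if i < j or (group_a != group_b and i != j):
                    if i != j:
                        vals.append(self.data[i, j])
        return float(np.mean(vals))


def occurrence_frequencies(
    table: CountTable, group: Sequence[str] | None = None
) -> np.ndarray:
    """Per-taxon occurrence frequency (number of group samples where present).

    Taxa absent from the whole group get weight 0 and can never enter a null
    community.
    """
    sub = table if group is None else table.select_samples(list(group))
    if sub.n_samples == 0:
        raise ValueError("empty group")
    return (sub.counts > 0).sum(axis=0).astype(float)


def _log_weights(weights: np.ndarray) -> np.ndarray:
    log_w = np.full(weights.shape, -np.inf)
    np.log(weights, out=log_w, where=weights > 0)
    return log_w


def _gumbel_topk(
    log_w: np.ndarray, richness: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """n_draws boolean null communities of exactly `richness` taxa each."""
    t = log_w.size
    out = np.zeros((n_draws, t), dtype=bool)
    if richness == 0:
        return out
    keys = log_w[None, :] + rng.gumbel(size=(n_draws, t))
    idx = np.argpartition(keys, t - richness, axis=1)[:, t - richness:]
    np.put_along_axis(out, idx, True, axis=1)
    return out


def null_community(
    richness: int, weights: np.ndarray, seed=None
) -> np.ndarray:
    """One null presence vector: `richness` distinct taxa, weight-proportional.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    n_pos = int((weights > 0).sum())
    if richness < 0 or richness > n_pos:
        raise ValueError(
            f"richness {richness} infeasible with {n_pos} positive-weight taxa"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log_w = _log_weights(weights)
    return _gumbel_topk(log_w, richness, 1, rng)[0]


def _split_tie_prob(j_null: np.ndarray, j_obs: int) -> float:
    n = j_null.size
    return float(((j_null > j_obs).sum() + 0.5 * (j_null == j_obs).sum()) / n)


def beta_rc_pair(
    a: np.ndarray, b: np.ndarray, weights: np.ndarray, config: NullConfig
) -> float:
    """Monte-Carlo βRC for one pair of presence vectors under shared weights."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    r_a, r_b = int(a.sum()), int(b.sum())
    n_pos = int((weights > 0).sum())
    if max(r_a, r_b) > n_pos:
        raise ValueError("observed richness exceeds positive-weight taxa")
    j_obs = int((a & b).sum())
    rng = np.random.default_rng(config.seed)
    log_w = _log_weights(weights)
    na = _gumbel_topk(log_w, r_a, config.n_simulations, rng)
    nb = _gumbel_topk(log_w, r_b, config.n_simulations, rng)
    j_null = (na & nb).sum(axis=1)
    return _split_tie_prob(j_null, j_obs)


def _scope_beta_rc(
    presence: np.ndarray,
    scope_idx: np.ndarray,
    fill_pairs: list[tuple[int, int]],
    out: np.ndarray,
    n_sim: int,
    rng: np.random.Generator,
) -> None:
    """Fill βRC entries for `fill_pairs` using frequencies over `scope_idx`.

    One null community is drawn per scope sample per simulation; within a
    simulation, pair overlaps reuse those draws (the same economy the vegan
    implementation uses). The diagonal and duplicate-richness pairs remain
    unbiased because draws are independent across simulations and samples.
    """
    sub = presence[scope_idx]
    weights = sub.sum(axis=0).astype(float)
    log_w = _log_weights(weights)
    t = presence.shape[1]
    m = len(scope_idx)
    richness = sub.sum(axis=1)
    local = {int(s): k for k, s in enumerate(scope_idx)}
    diag_samples = sorted({local[i] for i, j in fill_pairs if i == j})
    j_null = np.empty((n_sim, m, m), dtype=np.int32)
    j_diag = {li: np.empty(n_sim, dtype=np.int32) for li in diag_samples}
    # chunk simulations to bound memory at large taxon counts
    chunk = max(1, int(2e7 // max(1, m * t)))
    start = 0
    while start < n_sim:
        nsc = min(chunk, n_sim - start)
        nulls = np.zeros((nsc, m, t), dtype=bool)
        for jj in range(m):
            nulls[:, jj, :] = _gumbel_topk(log_w, int(richness[jj]), nsc, rng)
        nf = nulls.astype(np.float32)
        j_null[start : start + nsc] = np.matmul(
            nf, nf.transpose(0, 2, 1)
        ).astype(np.int32)
        for li in diag_samples:
            # a pair of a sample with itself needs a second independent draw
            second = _gumbel_topk(log_w, int(richness[li]), nsc, rng)
            j_diag[li][start : start + nsc] = (nulls[:, li, :] & second).sum(axis=1)
        start += nsc
    for i, j in fill_pairs:
        li, lj = local[i], local[j]
        jn = j_diag[li] if li == lj else j_null[:, li, lj]
        j_obs = int((presence[i] & presence[j]).sum())
        val = _split_tie_prob(np.asarray(jn), j_obs)
        out[i, j] = out[j, i] = val


def beta_rc(
    table: CountTable,
    metadata: SampleMetadata | None = None,
    config: NullConfig = NullConfig(),
    groups: Sequence[str] | None = None,
) -> BetaRCResult:
    """Full pairwise βRC matrix with group-constrained null models.

    Within-group pairs use that group's occurrence frequencies; between-group
    pairs use frequencies over the union of the two groups. ``groups`` may be
    given directly as per-sample labels; otherwise they are resolved from
    ``metadata`` using the columns named in ``config.constraint``.
    """
    if groups is None:
        if metadata is None:
            raise ValueError("either metadata or explicit groups are required")
        groups = metadata.group_labels(table, list(config.constraint))
    groups = [str(g) for g in groups]
    if len(groups) != table.n_samples:
        raise ValueError("one group label per sample is required")
    n = table.n_samples
    presence = table.presence()
    out = np.zeros((n, n), dtype=float)
    rng = np.random.default_rng(config.seed)
    labels = sorted(set(groups))
    by_group = {g: np.flatnonzero([x == g for x in groups]) for g in labels}
    for gi, ga in enumerate(labels):
        for gb in labels[gi:]:
            if ga == gb:
                scope = by_group[ga]
                pairs = [
                    (int(scope[i]), int(scope[j]))
                    for i in range(len(scope))
                    for j in range(i, len(scope))
                ]
            else:
                scope = np.concatenate([by_group[ga], by_group[gb]])
                pairs = [
                    (int(i), int(j)) for i in by_group[ga] for j in by_group[gb]
                ]
            _scope_beta_rc(presence, scope, pairs, out, config.n_simulations, rng)
    return BetaRCResult(
        sample_ids=list(table.sample_ids),
        data=out,
        groups=groups,
        n_simulations=config.n_simulations,
        seed=config.seed,
    )


def analytic_rc_equal_freq(
    pool_size: int, richness_a: int, richness_b: int, j_obs: int
) -> float:
    """Exact βRC when all pool taxa are equally likely (hypergeometric null).

    P(J = j) = C(r_a, j) C(P - r_a, r_b - j) / C(P, r_b); βRC applies the
    split-ties rule to this distribution. Serves as the closed-form oracle for
    the Monte-Carlo estimator.
    """
    if pool_size < 0 or min(richness_a, richness_b) < 0:
        raise ValueError("negative arguments")
    if max(richness_a, richness_b) > pool_size:
        raise ValueError("richness exceeds pool size")
    j_max = min(richness_a, richness_b)
    j_min = max(0, richness_a + richness_b - pool_size)
    if not (j_min <= j_obs <= j_max):
        raise ValueError(f"j_obs {j_obs} infeasible for these richnesses")
    dist = hypergeom(M=pool_size, n=richness_a, N=richness_b)
    return float(dist.sf(j_obs) + 0.5 * dist.pmf(j_obs))
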