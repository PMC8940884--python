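"""Permutational multivariate ANOVA (PERMANOVA) on a distance matrix.

Sequential (Type I) sums of squares in the user-given factor order, computed
by projecting the Gower-centered matrix onto nested model spaces — the
behaviour of vegan's ``adonis``. Permutation p-values use the
observed-inclusive convention (1 + exceedances) / (1 + n_perm), permuting
whole-sample labels freely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import DistanceMatrix, gower_center
from .io_formats import SampleMetadata

__all__ = ["PermanovaResult", "permanova"]


@dataclass
class PermanovaResult:
    """ANOVA-style table for a PERMANOVA fit."""

    terms: list[str]
    df: dict[str, int]
    ss: dict[str, float]
    pseudo_f: dict[str, float]
    r_squared: dict[str, float]
    p_values: dict[str, float]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (
                t,
                self.df[t],
                self.ss[t],
                self.pseudo_f[t],
                self.r_squared[t],
                self.p_values[t],
            )
            for t in self.terms
        ]
        rows.append(
            (
                "Residual",
                self.residual_df,
                self.residual_ss,
                np.nan,
                self.residual_ss / self.total_ss,
                np.nan,
            )
        )
        rows.append((
            "Total",
            self.residual_df + sum(self.df.values()),
            self.total_ss,
            np.nan,
            1.0,
            np.nan,
        ))
        return pd.DataFrame(
            rows, columns=["term", "df", "ss", "pseudo_F", "R2", "p"]
        ).set_index("term")


def _dummy_columns(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValueError("factor has fewer than 2 levels")
    # full-rank coding: drop the first level (intercept is always present)
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x, and its rank."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > 1e-10 * max(1.0, s[0])).sum())
    u = u[:, :rank]
    return u @ u.T, rank


def _resolve_factors(
    factors, dm: DistanceMatrix, metadata: SampleMetadata | None
) -> list[tuple[str, np.ndarray]]:
    out: list[tuple[str, np.ndarray]] = []
    if isinstance(factors, pd.DataFrame):
        df = factors.loc[dm.sample_ids]
        return [(str(c), df[c].astype(str).to_numpy()) for c in df.columns]
    if isinstance(factors, dict):
        return [(str(k), np.asarray(v, dtype=str)) for k, v in factors.items()]
    # sequence of column names resolved through metadata
    if metadata is None:
        raise ValueError("metadata required when factors are column names")
    sub = metadata.records.loc[dm.sample_ids]
    return [(str(f), sub[f].astype(str).to_numpy()) for f in factors]


def permanova(
    dm: DistanceMatrix,
    factors,
    metadata: SampleMetadata | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Sequential PERMANOVA of ``dm`` against categorical factors, in order.

    Parameters
    ----------
    dm : DistanceMatrix
    factors : list of metadata column names, dict name -> labels, or DataFrame
        Term order determines the sequential SS decomposition.
    metadata : SampleMetadata, optional
        Required when ``factors`` is a list of column names.
    n_perm : int
        Number of free label permutations (default 999).
    seed : int, optional
    exhaustive : bool
        Enumerate all n! permutations instead of sampling; the p-value is then
        the exact fraction of permutations (identity included) with F at least
        the observed F. Only sensible for small n.
    """
    resolved = _resolve_factors(factors, dm, metadata)
    n = len(dm.sample_ids)
    names = [name for name, _ in resolved]
    g = gower_center(dm.data)
    total_ss = float(np.trace(g))

    x = np.ones((n, 1))
    hats: list[np.ndarray] = []
    ranks: list[int] = []
    h_prev, rank_prev = _hat(x)
    for name, labels in resolved:
        if len(labels) != n:
            raise ValueError(f"factor {name} has wrong length")
        x = np.hstack([x, _dummy_columns(labels)])
        h, rank = _hat(x)
        if rank - rank_prev == 0:
            raise ValueError(f"singular design: factor {name} adds no rank")
        hats.append(h - h_prev)
        ranks.append(rank - rank_prev)
        h_prev, rank_prev = h, rank
    resid_proj = np.eye(n) - h_prev
    resid_df = n - rank_prev
    if resid_df < 1:
        raise ValueError("no residual degrees of freedom")

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss = np.array([float(np.sum(p * gmat)) for p in hats])
        ss_res = float(np.sum(resid_proj * gmat))
        f = (ss / np.array(ranks)) / (ss_res / resid_df)
        return ss, f

    ss_obs, f_obs = term_stats(g)
    ss_res = total_ss - ss_obs.sum()

    exceed = np.zeros(len(names))
    if exhaustive:
        from itertools import permutations as _perms

        count = 0
        for perm in _perms(range(n)):
            _, f_perm = term_stats(g[np.ix_(perm, perm)])
            exceed += f_perm >= f_obs - 1e-12
            count += 1
        pvals = exceed / count
        n_perm = count
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            _, f_perm = term_stats(g[np.ix_(perm, perm)])
            exceed += f_perm >= f_obs - 1e-12
        pvals = (1.0 + exceed) / (1.0 + n_perm)

    return PermanovaResult(
        terms=names,
        df=dict(zip(names, ranks)),
        ss=dict(zip(names, map(float, ss_obs))),
        pseudo_f=dict(zip(names, map(float, f_obs))),
        r_squared={k: float(v / total_ss) for k, v in zip(names, ss_obs)},
        p_values=dict(zip(names, map(float, pvals))),
        residual_df=resid_df,
        residual_ss=float(ss_res),
        total_ss=total_ss,
        n_permutations=n_perm,
    )
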