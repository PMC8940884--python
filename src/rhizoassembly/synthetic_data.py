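"""Synthetic ASV-table generator emulating a millimetre-scale rhizosphere study.

The generator reproduces the statistical structure the downstream analysis
assumes, without any sequencing data:

* a shared soil species pool with log-normal relative abundances,
* deterministic plant selection (per-taxon affinities scaled by a selection
  strength) that differentiates root compartments from bulk soil,
* replicate-level heterogeneous selection (multiplicative log-normal noise on
  selection weights), the surrogate for priority effects / variable selection
  among replicate roots,
* rank-truncation of selection weights so root compartments carry reduced
  richness relative to soil,
* rhizoplane communities drawn as a random subset of their paired rhizosphere
  replicate,
* taxon guilds coupled through a per-replicate latent factor, planting
  co-occurrence structure that proportionality networks should recover.

Everything is driven by a single integer seed; identical configurations give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import CountTable, SampleMetadata, PLANTS

__all__ = [
    "GeneratorConfig",
    "SpeciesPool",
    "ConfigError",
    "build_pool",
    "build_random_tree",
    "simulate_soil",
    "simulate_root_compartment",
    "derive_rhizoplane",
    "generate_study",
]


class ConfigError(ValueError):
    """Raised when generator parameters violate their bounds."""


@dataclass(frozen=True)
class GeneratorConfig:
    """All simulation parameters for one synthetic study.

    Defaults mirror the study design: per plant species, 3 soil controls plus
    15 rhizosphere and 15 rhizoplane replicates, root sequencing depth above
    the 1801-read rarefaction floor used for the robustness check.
    """

    n_taxa: int = 3000
    n_soil: int = 3
    n_reps: int = 15
    depth_soil: int = 5000
    depth_root: int = 2000
    selection_strength: float = 0.5
    sigma_rep: float = 2.0
    richness_reduction: float = 0.05
    rhizoplane_subset_fraction: float = 0.7
    n_guilds: int = 5
    guild_fraction: float = 0.3
    guild_correlation: float = 0.5
    pool_sigma: float = 0.75
    soil_concentration: float = 500.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.n_taxa >= 2, "n_taxa must be >= 2"),
            (self.n_soil >= 1, "n_soil must be >= 1"),
            (self.n_reps >= 1, "n_reps must be >= 1"),
            (self.depth_soil >= 1, "depth_soil must be >= 1"),
            (self.depth_root >= 1, "depth_root must be >= 1"),
            (self.selection_strength >= 0, "selection_strength must be >= 0"),
            (self.sigma_rep >= 0, "sigma_rep must be >= 0"),
            (0 < self.richness_reduction <= 1, "richness_reduction must be in (0, 1]"),
            (
                0 < self.rhizoplane_subset_fraction <= 1,
                "rhizoplane_subset_fraction must be in (0, 1]",
            ),
            (self.n_guilds >= 0, "n_guilds must be >= 0"),
            (0 <= self.guild_fraction <= 1, "guild_fraction must be in [0, 1]"),
            (0 <= self.guild_correlation < 1, "guild_correlation must be in [0, 1)"),
            (self.pool_sigma > 0, "pool_sigma must be > 0"),
            (self.soil_concentration > 0, "soil_concentration must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        if self.root_richness() < 2:
            raise ConfigError(
                "richness_reduction leaves fewer than 2 taxa in root compartments"
            )

    def root_richness(self) -> int:
        """Number of taxa retained in each root replicate after truncation."""
        return math.ceil(self.richness_reduction * self.n_taxa)


@dataclass
class SpeciesPool:
    """The soil species pool root microbiota are recruited from."""

    taxon_ids: list[str]
    pool_rel_abundance: np.ndarray
    compartment_affinity: np.ndarray
    guild_id: np.ndarray  # 0 = no guild

    def __post_init__(self) -> None:
        p = np.asarray(self.pool_rel_abundance, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError("pool relative abundances must be >= 0 and sum to 1")
        self.pool_rel_abundance = p
        self.compartment_affinity = np.asarray(self.compartment_affinity, dtype=float)
        self.guild_id = np.asarray(self.guild_id, dtype=int)


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # keyed sub-streams so each operation has its own reproducible stream
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(stream,))
    )


def build_random_tree(taxon_ids: list[str], rng: np.random.Generator) -> TreeNode:
    """Pure-birth random topology over the taxa with exponential branch lengths."""
    nodes = [TreeNode(name=t, length=float(rng.exponential(0.1))) for t in taxon_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = TreeNode(length=float(rng.exponential(0.1)))
        parent.extend([nodes[i], nodes[j]])
        nodes[i] = parent
        nodes.pop(j)
    root = nodes[0]
    root.length = None
    return root


def build_pool(config: GeneratorConfig) -> tuple[SpeciesPool, TreeNode]:
    """Draw the species pool and a random phylogeny over its taxa."""
    rng = _rng(config, 0)
    taxon_ids = [f"ASV{i + 1:04d}" for i in range(config.n_taxa)]
    logs = rng.normal(0.0, config.pool_sigma, size=config.n_taxa)
    abund = np.exp(logs)
    abund /= abund.sum()
    affinity = rng.normal(0.0, 1.0, size=config.n_taxa)
    guild_id = np.zeros(config.n_taxa, dtype=int)
    n_guilded = int(round(config.guild_fraction * config.n_taxa))
    if config.n_guilds > 0 and n_guilded > 0:
        members = rng.choice(config.n_taxa, size=n_guilded, replace=False)
        # round-robin so guilds have near-equal size
        guild_id[members] = 1 + (np.arange(n_guilded) % config.n_guilds)
    tree = build_random_tree(taxon_ids, _rng(config, 1))
    pool = SpeciesPool(taxon_ids, abund, affinity, guild_id)
    return pool, tree


def _multinomial_rows(
    proportions: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    return np.vstack([rng.multinomial(depth, p) for p in proportions])


def simulate_soil(
    pool: SpeciesPool,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
) -> CountTable:
    """Soil control samples: Dirichlet-perturbed pool proportions, multinomial reads.

    The Dirichlet concentration ``soil_concentration`` scales overdispersion:
    large values give samples tightly clustered around the pool composition.
    """
    rng = _rng(config, 2) if rng is None else rng
    alpha = pool.pool_rel_abundance * config.soil_concentration
    # gamma construction: dirichlet with potentially tiny alphas, safely
    gams = rng.gamma(np.broadcast_to(alpha, (config.n_soil, config.n_taxa)))
    props = gams / gams.sum(axis=1, keepdims=True)
    counts = _multinomial_rows(props, config.depth_soil, rng)
    ids = sample_ids or [f"soil_{i + 1}" for i in range(config.n_soil)]
    return CountTable(ids, list(pool.taxon_ids), counts)


def _selection_weights(
    pool: SpeciesPool, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-replicate selection weights over taxa (n_reps x n_taxa)."""
    s, sigma = config.selection_strength, config.sigma_rep
    base = pool.pool_rel_abundance * np.exp(s * pool.compartment_affinity)
    log_w = np.log(base)[None, :] + rng.normal(
        0.0, sigma if sigma > 0 else 0.0, size=(config.n_reps, config.n_taxa)
    )
    if config.guild_correlation > 0 and config.n_guilds > 0 and sigma > 0:
        # scale the shared latent factor so the log-weight correlation between
        # two members of the same guild equals guild_correlation
        gc = config.guild_correlation
        sigma_guild = sigma * math.sqrt(gc / (1.0 - gc))
        z = rng.normal(size=(config.n_reps, config.n_guilds + 1))
        z[:, 0] = 0.0  # guild 0 = unguilded, no shared factor
        log_w += sigma_guild * z[:, pool.guild_id]
    return np.exp(log_w)


def simulate_root_compartment(
    pool: SpeciesPool,
    config: GeneratorConfig,
    compartment: str = "rhizosphere",
    rng: np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
) -> CountTable:
    """Rhizosphere replicates assembled by two-step selection from the pool.

    Weights combine the pool abundance, deterministic plant selection, the
    replicate-specific heterogeneity term and guild coupling; the lowest-weight
    taxa are then truncated so each replicate keeps exactly
    ``ceil(richness_reduction * n_taxa)`` taxa before sequencing.
    """
    if compartment != "rhizosphere":
        raise ValueError(
            "only 'rhizosphere' is simulated directly; use derive_rhizoplane"
        )
    rng = _rng(config, 3) if rng is None else rng
    weights = _selection_weights(pool, config, rng)
    keep = config.root_richness()
    if keep < 2:
        raise ConfigError("richness_reduction leaves fewer than 2 taxa")
    # rank-truncation: zero all but the `keep` largest weights per replicate
    order = np.argsort(weights, axis=1)
    for r in range(config.n_reps):
        weights[r, order[r, : config.n_taxa - keep]] = 0.0
    props = weights / weights.sum(axis=1, keepdims=True)
    counts = _multinomial_rows(props, config.depth_root, rng)
    ids = sample_ids or [f"{compartment}_{i + 1}" for i in range(config.n_reps)]
    return CountTable(ids, list(pool.taxon_ids), counts)


def derive_rhizoplane(
    rhizosphere_table: CountTable,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
) -> CountTable:
    """Rhizoplane replicates as a uniform random subset of the paired rhizosphere.

    For each replicate a fraction of the taxa present in the rhizosphere sample
    is retained uniformly at random, proportions are renormalized, and reads are
    redrawn at ``depth_root``.
    """
    rng = _rng(config, 4) if rng is None else rng
    frac = config.rhizoplane_subset_fraction
    out = np.zeros_like(rhizosphere_table.counts)
    for r in range(rhizosphere_table.n_samples):
        present = np.flatnonzero(rhizosphere_table.counts[r] > 0)
        n_keep = math.ceil(frac * present.size)
        if n_keep < 1:
            raise ConfigError(
                f"rhizoplane_subset_fraction leaves no taxa for replicate {r + 1}"
            )
        kept = rng.choice(present, size=n_keep, replace=False)
        p = rhizosphere_table.counts[r, kept].astype(float)
        out[r, kept] = rng.multinomial(config.depth_root, p / p.sum())
    ids = sample_ids or [
        s.replace("rhizosphere", "rhizoplane") for s in rhizosphere_table.sample_ids
    ]
    return CountTable(ids, list(rhizosphere_table.taxon_ids), out)


def generate_study(
    config: GeneratorConfig,
) -> tuple[CountTable, SampleMetadata, TreeNode]:
    """Generate the full two-plant study: per plant, soil + rhizosphere + rhizoplane.

    Returns one combined count table (33 samples per plant under defaults),
    matching metadata and the shared phylogeny. Both plants recruit from the
    same species pool but carry independent compartment affinities, so plant
    identity separates root communities while soils remain exchangeable.
    """
    pool, tree = build_pool(config)
    tables: list[CountTable] = []
    meta_rows: list[dict] = []
    for p_idx, plant in enumerate(PLANTS):
        plant_pool = pool
        if p_idx > 0:
            aff = _rng(config, 10 + p_idx).normal(0.0, 1.0, size=config.n_taxa)
            plant_pool = replace(pool, compartment_affinity=aff)
        soil = simulate_soil(
            plant_pool,
            config,
            rng=_rng(config, 20 + p_idx),
            sample_ids=[f"{plant}_soil_{i + 1}" for i in range(config.n_soil)],
        )
        rhizo = simulate_root_compartment(
            plant_pool,
            config,
            rng=_rng(config, 30 + p_idx),
            sample_ids=[
                f"{plant}_rhizosphere_{i + 1}" for i in range(config.n_reps)
            ],
        )
        plane = derive_rhizoplane(
            rhizo,
            config,
            rng=_rng(config, 40 + p_idx),
            sample_ids=[f"{plant}_rhizoplane_{i + 1}" for i in range(config.n_reps)],
        )
        for tbl, stype, n in (
            (soil, "soil", config.n_soil),
            (rhizo, "rhizosphere", config.n_reps),
            (plane, "rhizoplane", config.n_reps),
        ):
            tables.append(tbl)
            meta_rows.extend(
                {
                    "sample_id": sid,
                    "plant": plant,
                    "sample_type": stype,
                    "replicate": i + 1,
                }
                for i, sid in enumerate(tbl.sample_ids)
            )
    all_ids = [s for t in tables for s in t.sample_ids]
    counts = np.vstack([t.counts for t in tables])
    table = CountTable(all_ids, list(pool.taxon_ids), counts)
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return table, meta, tree
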