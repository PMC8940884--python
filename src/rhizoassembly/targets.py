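"""The two headline simulation quantities the package reproduces.

Both anchor the Raup-Crick analysis of the millimetre-scale root microbiome
study design:

* strong divergent selection between soil and rhizosphere saturates the
  between-group βRC at the metric's maximum of 1;
* strong replicate-level heterogeneous selection pushes within-group βRC to
  ~0.9, i.e. replicate communities are more different from each other than
  the richness-constrained null expects.

These functions are shared between the acceptance script and the test suite
so both always compute the quantities the same way, from scratch.
"""

from __future__ import annotations

import numpy as np

from .io_formats import PLANTS
from .raupcrick import NullConfig, beta_rc
from .synthetic_data import GeneratorConfig, generate_study

__all__ = ["soil_vs_rhizosphere_betarc", "within_rhizosphere_betarc"]


def soil_vs_rhizosphere_betarc(
    base_seed: int = 1,
    n_seeds: int = 3,
    n_simulations: int = 999,
) -> float:
    """Mean soil-vs-rhizosphere βRC under strong divergent selection.

    Generates studies with selection_strength=3 and richness_reduction=0.3
    (defaults otherwise) and averages the soil-vs-rhizosphere group-mean βRC
    (999 null simulations, union-scope occurrence frequencies) over both plant
    species and ``n_seeds`` generator seeds.
    """
    vals = []
    for k in range(n_seeds):
        cfg = GeneratorConfig(
            selection_strength=3.0,
            richness_reduction=0.3,
            rng_seed=(base_seed + k) % 2**31,
        )
        table, meta, _ = generate_study(cfg)
        for plant in PLANTS:
            sub = table.select_samples(meta.subset(plant=plant))
            groups = meta.group_labels(sub, ["sample_type"])
            rc = beta_rc(
                sub,
                config=NullConfig(n_simulations=n_simulations, seed=cfg.rng_seed + 100),
                groups=groups,
            )
            vals.append(rc.group_mean("soil", "rhizosphere"))
    return float(np.mean(vals))


def within_rhizosphere_betarc(
    base_seed: int = 1,
    n_seeds: int = 10,
    n_simulations: int = 999,
) -> float:
    """Grand mean within-rhizosphere βRC under heterogeneous selection.

    Generates ``n_seeds`` studies with sigma_rep=2 (the default) and
    guild_correlation=0, computes the mean pairwise within-group βRC over the
    15 wheat rhizosphere replicates for each, and averages across seeds.
    """
    vals = []
    for k in range(n_seeds):
        cfg = GeneratorConfig(
            guild_correlation=0.0, rng_seed=(base_seed + k) % 2**31
        )
        table, meta, _ = generate_study(cfg)
        ids = meta.subset(plant="wheat", sample_type="rhizosphere")
        sub = table.select_samples(ids)
        rc = beta_rc(
            sub,
            config=NullConfig(n_simulations=n_simulations, seed=cfg.rng_seed + 100),
            groups=["rhizosphere"] * len(ids),
        )
        vals.append(rc.group_mean("rhizosphere", "rhizosphere"))
    return float(np.mean(vals))
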