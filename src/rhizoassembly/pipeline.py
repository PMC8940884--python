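"""End-to-end orchestration: data → diversity → PERMANOVA → βRC → networks.

A single master seed drives every stage through a fixed keyed derivation, so
rerunning the same configuration reproduces every output checksum, and adding
a stage can never perturb the random stream of an earlier one.

The pipeline also runs a rarefaction robustness branch: the same analyses on a
dataset rarefied to a fixed depth (default 1801 reads/sample), reporting
whether the qualitative conclusions — the sign of the soil-vs-root richness
difference, whether βRC group means sit above or below 0.5, and the
edge-count significance call — agree with the non-rarefied run.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import io_formats as iof
from .cooccurrence import edge_count_test, network_pipeline, topology_report
from .io_formats import CountTable, SampleMetadata
from .permanova import permanova
from .raupcrick import NullConfig, beta_rc
from .synthetic_data import GeneratorConfig, generate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ("data", "diversity", "permanova", "betarc", "cooccurrence")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input mode, per-stage parameters and the master seed."""

    output_dir: str | Path = "rhizoassembly_out"
    mode: str = "synthetic"  # "synthetic" | "files"
    generator: GeneratorConfig | None = None
    table_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    n_permutations: int = 999
    n_simulations: int = 999
    n_null: int = 99
    threshold: float = 0.6
    min_total: int = 50
    rarefaction_depth: int = 1801
    rarefied_check: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "synthetic" and self.generator is None:
            self.generator = GeneratorConfig(rng_seed=self.stage_seed(0))

    def stage_seed(self, stage_index: int) -> int:
        """Keyed per-stage seed derived from the master seed."""
        ss = np.random.SeedSequence(
            entropy=int(self.master_seed), spawn_key=(int(stage_index),)
        )
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.mode == "synthetic":
        return generate_study(config.generator)
    for label, p in (
        ("table", config.table_path),
        ("metadata", config.metadata_path),
        ("tree", config.tree_path),
    ):
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"missing input {label} file: {p}")
    return (
        iof.read_count_table(config.table_path),
        iof.read_metadata(config.metadata_path),
        iof.read_tree(config.tree_path),
    )


def _qualitative_summary(
    table: CountTable,
    metadata: SampleMetadata,
    config: PipelineConfig,
    seed_offset: int,
) -> dict:
    """The qualitative conclusions compared between rarefied/non-rarefied runs."""
    records = dv.alpha_diversity(table)
    rich = {r.sample_id: r.observed_richness for r in records}
    soil = [rich[s] for s in metadata.subset(sample_type="soil") if s in rich]
    root = [
        rich[s]
        for t in ("rhizosphere", "rhizoplane")
        for s in metadata.subset(sample_type=t)
        if s in rich
    ]
    out = {"root_richness_below_soil": float(np.mean(root)) < float(np.mean(soil))}
    nc = NullConfig(
        n_simulations=config.n_simulations,
        constraint=("plant", "sample_type"),
        seed=config.stage_seed(300 + seed_offset),
    )
    rc = beta_rc(table, metadata, nc)
    for plant in iof.PLANTS:
        g = f"{plant}/rhizosphere"
        out[f"betarc_within_{plant}_rhizosphere_above_0.5"] = (
            rc.group_mean(g, g) > 0.5
        )
        out[f"betarc_{plant}_soil_vs_rhizosphere_above_0.5"] = (
            rc.group_mean(f"{plant}/soil", g) > 0.5
        )
    for plant in iof.PLANTS:
        ids = metadata.subset(plant=plant, sample_type="rhizosphere")
        ids = [s for s in ids if s in table.sample_ids]
        if len(ids) >= 3:
            sub = table.select_samples(ids)
            res = edge_count_test(
                sub,
                n_null=config.n_null,
                threshold=config.threshold,
                min_total=config.min_total,
                seed=config.stage_seed(400 + seed_offset),
            )
            out[f"edges_{plant}_rhizosphere_significant"] = res.empirical_p <= 0.05
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write outputs + manifest, return the manifest mapping."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"master_seed": config.master_seed}
    outputs: list[Path] = []
    t0 = time.time()

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        outputs.append(path)
        return path

    stage = "data"
    try:
        table, metadata, tree = _load_inputs(config)
        emit("counts.tsv", lambda p: iof.write_count_table(table, p))
        emit("metadata.tsv", lambda p: iof.write_metadata(metadata, p))
        emit("tree.nwk", lambda p: iof.write_tree(tree, p))
        if config.mode == "synthetic":
            for k, v in vars(config.generator).items():
                manifest[f"generator.{k}"] = v

        stage = "diversity"
        records = dv.alpha_diversity(table)
        emit("alpha.tsv", lambda p: dv.alpha_table(records).to_csv(p, sep="\t"))
        tests = dv.group_tests(records, metadata, factor="sample_type")
        emit(
            "alpha_tests.tsv",
            lambda p: tests["pairwise"].to_csv(p, sep="\t", index=False),
        )
        manifest["alpha.kruskal_p"] = tests["kruskal_p"]
        dms = {
            "bray_curtis": dv.bray_curtis(table),
            "unweighted_unifrac": dv.unweighted_unifrac(table, tree),
            "weighted_unifrac": dv.weighted_unifrac(table, tree),
        }
        for name, dm in dms.items():
            emit(f"distance_{name}.tsv", lambda p, d=dm: d.to_dataframe().to_csv(p, sep="\t"))
            ordi = dv.pcoa(dm)
            coords = pd.DataFrame(
                ordi.coordinates,
                index=ordi.sample_ids,
                columns=[f"PCo{i + 1}" for i in range(ordi.coordinates.shape[1])],
            )
            emit(f"pcoa_{name}.tsv", lambda p, c=coords: c.to_csv(p, sep="\t"))

        stage = "permanova"
        for name, dm in dms.items():
            res = permanova(
                dm,
                ["plant", "sample_type"],
                metadata=metadata,
                n_perm=config.n_permutations,
                seed=config.stage_seed(2),
            )
            emit(
                f"permanova_{name}.tsv",
                lambda p, r=res: r.to_dataframe().to_csv(p, sep="\t"),
            )
            for term in res.terms:
                manifest[f"permanova.{name}.{term}.R2"] = round(
                    res.r_squared[term], 6
                )
                manifest[f"permanova.{name}.{term}.p"] = res.p_values[term]

        stage = "betarc"
        nc = NullConfig(
            n_simulations=config.n_simulations,
            constraint=("plant", "sample_type"),
            seed=config.stage_seed(3),
        )
        rc = beta_rc(table, metadata, nc)
        emit("betarc.tsv", lambda p: rc.to_dataframe().to_csv(p, sep="\t"))
        summary_rows = []
        labels = sorted(set(rc.groups))
        for i, ga in enumerate(labels):
            for gb in labels[i:]:
                summary_rows.append(
                    {"group_a": ga, "group_b": gb, "mean_betarc": rc.group_mean(ga, gb)}
                )
        summary = pd.DataFrame(summary_rows)
        emit("betarc_group_means.tsv", lambda p: summary.to_csv(p, sep="\t", index=False))

        stage = "cooccurrence"
        networks = {}
        for plant in iof.PLANTS:
            for comp in ("rhizosphere", "rhizoplane"):
                ids = [
                    s
                    for s in metadata.subset(plant=plant, sample_type=comp)
                    if s in table.sample_ids
                ]
                if len(ids) < 3:
                    continue
                sub = table.select_samples(ids)
                key = f"{plant}_{comp}"
                net = network_pipeline(
                    sub,
                    threshold=config.threshold,
                    min_total=config.min_total,
                )
                networks[key] = net
                emit(f"network_{key}.tsv", lambda p, n=net: iof.write_edge_list(n, p))
                dist = edge_count_test(
                    sub,
                    n_null=config.n_null,
                    threshold=config.threshold,
                    min_total=config.min_total,
                    seed=config.stage_seed(4),
                )
                emit(
                    f"null_edges_{key}.tsv",
                    lambda p, d=dist: pd.DataFrame(
                        {"null_edge_count": d.null_edge_counts}
                    ).to_csv(p, sep="\t", index=False),
                )
                manifest[f"cooccurrence.{key}.observed_edges"] = dist.observed_edge_count
                manifest[f"cooccurrence.{key}.empirical_p"] = dist.empirical_p
        if networks:
            emit(
                "network_topology.tsv",
                lambda p: topology_report(networks).to_csv(p, sep="\t"),
            )

        if config.rarefied_check:
            stage = "rarefaction_robustness"
            base = _qualitative_summary(table, metadata, config, 0)
            rare = dv.rarefy(
                table, config.rarefaction_depth, seed=config.stage_seed(5)
            )
            rare_summary = _qualitative_summary(rare, metadata, config, 1)
            rows = [
                {
                    "conclusion": k,
                    "non_rarefied": base[k],
                    "rarefied": rare_summary.get(k),
                    "agrees": base[k] == rare_summary.get(k),
                }
                for k in base
            ]
            rob = pd.DataFrame(rows)
            emit(
                "rarefaction_robustness.tsv",
                lambda p: rob.to_csv(p, sep="\t", index=False),
            )
            manifest["rarefaction.depth"] = config.rarefaction_depth
            manifest["rarefaction.all_agree"] = bool(rob["agrees"].all())
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    import rhizoassembly

    manifest["version"] = rhizoassembly.__version__
    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    for path in outputs:
        manifest[f"sha256.{path.name}"] = _sha256(path)
    lines = [f"{k}={manifest[k]}" for k in manifest]
    (out_dir / "manifest.txt").write_text("\n".join(lines) + "\n")
    return manifest
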