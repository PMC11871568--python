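"""End-to-end orchestration: config, stage wiring, and run manifests.

Two pipelines are wired here. The kinome pipeline runs
simulate/load kinetics -> slope extraction + QC -> per-comparison fold
changes and differential sets -> sampling-null upstream-kinase statistics
-> kinome summary. The transcriptome pipeline runs simulate/load contrast
tables -> dual-contrast partition -> dependence ranking -> optional GMT
enrichment. Every run writes a manifest with a config hash and SHA-256
checksums of all artifacts, so deterministic stages can be verified to
reproduce bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as kio
from .contrast import (
    dependence_scores,
    enrich,
    partition_genes,
    read_gmt,
)
from .design import ExperimentDesign, NoiseModel, PlantedEffect
from .differential import (
    GroupComparison,
    fold_change,
    groups_from_metadata,
    select_differential,
)
from .kinase import KinaseSubstrateMap, analyze_comparison, summarize_kinome
from .panels import default_panel
from .signal import extract_signals
from .synthetic import generate_kinase_map, simulate_chip_run, simulate_contrast_tables

__version__ = "0.1.0"

logger = logging.getLogger("kinomeflow")


@dataclass
class RunConfig:
    """All tunable parameters of both pipelines, YAML round-trippable.

    Defaults equal the published analysis parameters: R^2 >= 0.80,
    FC thresholds 1.30 / 0.70, 2000 sampling iterations, padj < .05,
    top/bottom 100.
    """

    seed: int = 0
    out_dir: str = "runs/demo"
    synthetic: bool = True
    # --- chip synthesis ---
    panel: str = "STK"
    n_kinases: int = 20
    substrates_per_kinase: tuple[int, int] = (5, 15)
    overlap_fraction: float = 0.3
    genotypes: tuple[str, ...] = ("Scramble", "INSR_KO")
    treatments: tuple[str, ...] = ("Vehicle", "Insulin", "TGFb")
    replicates_per_cell: int = 3
    intensity_cv: float = 0.1
    background_level: float = 50.0
    saturation_ceiling: float | None = None
    effects: list[dict[str, Any]] = field(default_factory=list)
    # --- file inputs (used when synthetic = False) ---
    kinetics_path: str | None = None
    metadata_path: str | None = None
    kinase_map_path: str | None = None
    contrast_a_path: str | None = None
    contrast_b_path: str | None = None
    gmt_path: str | None = None
    # --- signal stage ---
    r2_min: float = 0.80
    slope_floor: float = 1e-6
    exposure: float | None = None
    # --- differential stage ---
    fc_up: float = 1.30
    fc_down: float = 0.70
    # --- upstream kinase stage ---
    iterations: int = 2000
    min_substrates: int = 3
    # --- transcriptome stage ---
    padj_cutoff: float = 0.05
    top_n: int = 100
    # --- contrast synthesis ---
    n_genes: int = 2000
    n_shared_up: int = 299
    n_shared_down: int = 364
    n_opposite: int = 4
    n_unique_each: int = 100
    effect_log2fc: float = 2.0
    null_sd: float = 0.25
    # --- comparisons: list of {name, group_a: {genotype, treatment}, group_b: {...}} ---
    comparisons: list[dict[str, Any]] = field(
        default_factory=lambda: [
            {
                "name": "KO_TGFb_vs_Scramble_TGFb",
                "group_a": {"genotype": "INSR_KO", "treatment": "TGFb"},
                "group_b": {"genotype": "Scramble", "treatment": "TGFb"},
            }
        ]
    )

    def __post_init__(self) -> None:
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must lie in [0, 1]")
        if not (self.fc_up > 1 > self.fc_down > 0):
            raise ValueError("fc thresholds must satisfy fc_up > 1 > fc_down > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.padj_cutoff < 1:
            raise ValueError("padj_cutoff must lie in (0, 1)")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.min_substrates < 1:
            raise ValueError("min_substrates must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["substrates_per_kinase"] = list(self.substrates_per_kinase)
        d["genotypes"] = list(self.genotypes)
        d["treatments"] = list(self.treatments)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs = dict(d)
        for key in ("substrates_per_kinase", "genotypes", "treatments"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    pipeline: str
    config_hash: str
    version: str
    timestamp: str
    files: dict[str, str]  # relative path -> sha256

    def to_json(self, path: str | Path) -> None:
        kio.write_json(dataclasses.asdict(self), path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest(pipeline: str, config: RunConfig, out_dir: Path, files: list[Path]) -> RunManifest:
    manifest = RunManifest(
        pipeline=pipeline,
        config_hash=config.config_hash(),
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        files={str(p.relative_to(out_dir)): _sha256(p) for p in sorted(files)},
    )
    manifest.to_json(out_dir / f"manifest_{pipeline}.json")
    return manifest


def _require(value: Any, name: str) -> Any:
    if value is None:
        raise ValueError(f"config field {name!r} is required when synthetic = False")
    return value


def _child_seed(seed: int, tag: int) -> int:
    # stable small child seeds for per-stage generators
    return (seed * 1000003 + tag) % (2**31 - 1)


def run_kinome_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the kinome stages end to end; returns the run manifest."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.time()

    if config.synthetic:
        panel = default_panel(config.panel)
        kmap = generate_kinase_map(
            config.n_kinases,
            panel,
            substrates_per_kinase=config.substrates_per_kinase,
            overlap_fraction=config.overlap_fraction,
            seed=_child_seed(config.seed, 1),
        )
        design = ExperimentDesign(
            genotypes=config.genotypes,
            treatments=config.treatments,
            replicates_per_cell=config.replicates_per_cell,
        )
        effects = [
            PlantedEffect(
                kinase_id=e["kinase_id"],
                condition=(e["genotype"], e["treatment"]),
                activity_multiplier=float(e["activity_multiplier"]),
            )
            for e in config.effects
        ]
        noise = NoiseModel(
            intensity_cv=config.intensity_cv,
            background_level=config.background_level,
            saturation_ceiling=config.saturation_ceiling,
        )
        sim = simulate_chip_run(
            design, panel, kmap, effects, noise, seed=_child_seed(config.seed, 2)
        )
        kinetics, metadata = sim.kinetics, sim.metadata
        kio.write_tsv(kinetics, out / "kinetics.tsv")
        kio.write_tsv(metadata, out / "metadata.tsv")
        kmap.to_tsv(out / "kinase_map.tsv")
        truth = sim.effective_velocity.reset_index()
        kio.write_tsv(truth, out / "truth_velocities.tsv")
        written += [out / "kinetics.tsv", out / "metadata.tsv", out / "kinase_map.tsv",
                    out / "truth_velocities.tsv"]
    else:
        kinetics = kio.read_kinetics(_require(config.kinetics_path, "kinetics_path"))
        metadata = kio.read_metadata(_require(config.metadata_path, "metadata_path"))
        kmap = KinaseSubstrateMap.from_tsv(_require(config.kinase_map_path, "kinase_map_path"))

    signals = extract_signals(
        kinetics, r2_min=config.r2_min, slope_floor=config.slope_floor, exposure=config.exposure
    )
    kio.write_tsv(signals, out / "signals.tsv")
    written.append(out / "signals.tsv")
    logger.info("signal extraction done in %.1fs (%d series)", time.time() - t0, len(signals))

    all_stats: list[pd.DataFrame] = []
    for i, spec in enumerate(config.comparisons):
        cmp = GroupComparison(
            name=spec["name"],
            group_a=groups_from_metadata(metadata, **spec["group_a"]),
            group_b=groups_from_metadata(metadata, **spec["group_b"]),
        )
        fc = fold_change(signals, cmp)
        kio.write_tsv(fc, out / f"fold_changes_{cmp.name}.tsv")
        diff = select_differential(
            fc, name=cmp.name, up_threshold=config.fc_up, down_threshold=config.fc_down
        )
        kio.write_differential_set(diff, out / f"differential_{cmp.name}.json")
        stats = analyze_comparison(
            diff,
            fc,
            kmap,
            iterations=config.iterations,
            seed=_child_seed(config.seed, 10 + i),
            min_substrates=config.min_substrates,
        )
        stats.insert(0, "comparison", cmp.name)
        kio.write_tsv(stats, out / f"kinase_stats_{cmp.name}.tsv")
        # per-substrate fold changes of each retained kinase, for activity plots
        rows = []
        lfc = fc.set_index("peptide_id")["log2fc"]
        for kin in stats["kinase_id"]:
            for p in sorted(kmap.substrates(kin) & diff.background):
                rows.append({"kinase_id": kin, "peptide_id": p, "log2fc": lfc[p]})
        kio.write_tsv(pd.DataFrame(rows), out / f"substrate_log2fc_{cmp.name}.tsv")
        written += [
            out / f"fold_changes_{cmp.name}.tsv",
            out / f"differential_{cmp.name}.json",
            out / f"kinase_stats_{cmp.name}.tsv",
            out / f"substrate_log2fc_{cmp.name}.tsv",
        ]
        all_stats.append(stats)
        logger.info(
            "comparison %s: %d background, %d differential, %d kinases",
            cmp.name, len(diff.background), len(diff.differential), len(stats),
        )

    summary = summarize_kinome(pd.concat(all_stats, ignore_index=True)) if all_stats else pd.DataFrame()
    kio.write_tsv(summary, out / "kinome_summary.tsv")
    written.append(out / "kinome_summary.tsv")
    return _manifest("kinome", config, out, written)


def run_transcriptome_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the transcriptome stages end to end; returns the run manifest."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if config.synthetic:
        a, b, truth = simulate_contrast_tables(
            n_genes=config.n_genes,
            n_shared_up=config.n_shared_up,
            n_shared_down=config.n_shared_down,
            n_opposite=config.n_opposite,
            n_unique_each=config.n_unique_each,
            effect_log2fc=config.effect_log2fc,
            null_sd=config.null_sd,
            seed=_child_seed(config.seed, 3),
        )
        kio.write_tsv(a, out / "contrast_a.tsv")
        kio.write_tsv(b, out / "contrast_b.tsv")
        kio.write_tsv(truth, out / "truth_labels.tsv")
        written += [out / "contrast_a.tsv", out / "contrast_b.tsv", out / "truth_labels.tsv"]
    else:
        a = kio.read_contrast(_require(config.contrast_a_path, "contrast_a_path"))
        b = kio.read_contrast(_require(config.contrast_b_path, "contrast_b_path"))

    if a.empty or b.empty:
        logger.warning("empty contrast table(s); writing empty outputs")
        kio.write_json({"counts": {}, "sets": {}}, out / "partition.json")
        written.append(out / "partition.json")
        return _manifest("transcriptome", config, out, written)

    part = partition_genes(a, b, padj_cutoff=config.padj_cutoff)
    kio.write_json({"counts": part.counts(), "sets": part.to_dict()}, out / "partition.json")
    counts_df = pd.DataFrame([part.counts()])
    kio.write_tsv(counts_df, out / "partition_counts.tsv")
    ranking = dependence_scores(a, b, top_n=config.top_n)
    scores_df = ranking.scores.reset_index()
    kio.write_tsv(scores_df, out / "dependence_scores.tsv")
    lists_df = pd.DataFrame(
        {
            "rank": range(1, len(ranking.top) + 1),
            "top_gene": ranking.top,
            "bottom_gene": ranking.bottom,
        }
    )
    kio.write_tsv(lists_df, out / "dependence_top_bottom.tsv")
    written += [
        out / "partition.json",
        out / "partition_counts.tsv",
        out / "dependence_scores.tsv",
        out / "dependence_top_bottom.tsv",
    ]

    if config.gmt_path is not None:
        gene_sets = read_gmt(config.gmt_path)
        universe = set(a["gene_id"]) & set(b["gene_id"])
        for label, query in (("top", ranking.top), ("bottom", ranking.bottom)):
            res = enrich(query, gene_sets, universe)
            kio.write_tsv(res, out / f"enrichment_{label}.tsv")
            written.append(out / f"enrichment_{label}.tsv")
    return _manifest("transcriptome", config, out, written)
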