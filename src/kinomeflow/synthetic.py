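"""Planted-truth synthetic data: kinome-chip kinetics and gene contrast tables.

Every downstream stage of the pipeline is testable without any download
because this module generates its inputs with known ground truth:

* a kinase -> reporter-peptide substrate annotation,
* kinetic multi-exposure intensity tables from a chip run in which chosen
  kinases have their activity multiplied in chosen conditions,
* paired per-gene contrast tables with planted shared / opposite /
  condition-specific responder genes.

Signal model of the chip: each peptide p has a baseline phosphorylation
velocity v_p (log-uniform across peptides, ~2 orders of magnitude). In a
sample whose (genotype, treatment) carries planted effects, the velocity
is multiplied by the product of the activity multipliers of all affected
kinases that target p. The noiseless observed intensity is

    background + v_p * m * t * (exposure_ms / 100)

i.e. linear in cycle time t and proportional to CCD exposure, which is
exactly the structure the slope-extraction stage assumes. Noise is
mean-one multiplicative lognormal on each observation; an optional
saturation ceiling clips after noise.

One global seed expands into fixed, independent child streams per stage,
so each generator is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExperimentDesign, NoiseModel, PlantedEffect
from .kinase import KinaseSubstrateMap
from .panels import PanelDefinition

# fixed spawn keys for per-stage child seeds
_STREAM_MAP = 1
_STREAM_CHIP = 2
_STREAM_CONTRAST = 3

DEFAULT_VELOCITY_RANGE = (1.0, 100.0)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def generate_kinase_map(
    n_kinases: int,
    panel: PanelDefinition,
    substrates_per_kinase: tuple[int, int] = (5, 15),
    overlap_fraction: float = 0.3,
    seed: int = 0,
) -> KinaseSubstrateMap:
    """Draw a random kinase -> substrate annotation over a panel.

    Each kinase receives a substrate count uniform in
    ``substrates_per_kinase`` (inclusive). A fraction ``overlap_fraction``
    of each kinase's substrates is drawn from peptides already assigned to
    earlier kinases (promoting sharing); the remainder comes preferentially
    from never-used peptides, falling back to the whole panel once the
    panel is exhausted. With overlap 0 and total demand within the panel
    size, substrate sets are fully disjoint.
    """
    lo, hi = substrates_per_kinase
    if n_kinases < 1:
        raise ValueError("n_kinases must be >= 1")
    if lo < 1 or hi < lo:
        raise ValueError("substrates_per_kinase must be a nondecreasing range with min >= 1")
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if hi > len(panel):
        raise ValueError(
            f"requested up to {hi} substrates but panel has only {len(panel)} peptides"
        )
    if overlap_fraction == 0 and n_kinases * lo > len(panel):
        raise ValueError(
            "disjoint substrate sets requested (overlap 0) but minimum total demand "
            f"{n_kinases * lo} exceeds panel size {len(panel)}"
        )
    rng = _rng(seed, _STREAM_MAP)
    panel_ids = list(panel.peptide_ids)
    unused = list(panel_ids)
    assigned_union: list[str] = []
    pairs: list[tuple[str, str]] = []
    for i in range(1, n_kinases + 1):
        kin = f"KIN_{i:03d}"
        n = int(rng.integers(lo, hi + 1))
        n_shared = min(int(round(overlap_fraction * n)), len(assigned_union))
        chosen: list[str] = []
        if n_shared:
            chosen.extend(rng.choice(assigned_union, size=n_shared, replace=False))
        n_rest = n - len(chosen)
        fresh_pool = [p for p in unused if p not in chosen]
        if n_rest <= len(fresh_pool):
            chosen.extend(rng.choice(fresh_pool, size=n_rest, replace=False))
        else:
            chosen.extend(fresh_pool)
            fallback = [p for p in panel_ids if p not in chosen]
            short = n - len(chosen)
            if short > len(fallback):
                raise ValueError("substrate demand exceeds panel size")
            chosen.extend(rng.choice(fallback, size=short, replace=False))
        for p in chosen:
            pairs.append((kin, p))
            if p in unused:
                unused.remove(p)
            if p not in assigned_union:
                assigned_union.append(p)
    return KinaseSubstrateMap(pairs)


@dataclass
class ChipSimulation:
    """A simulated chip run plus its ground truth."""

    kinetics: pd.DataFrame       # peptide_id, sample_id, cycle_time_min, exposure_ms, intensity
    metadata: pd.DataFrame       # sample_id, genotype, treatment, replicate
    baseline_velocity: pd.Series  # per peptide_id
    effective_velocity: pd.DataFrame  # peptide x sample true velocity (after multipliers)


def simulate_chip_run(
    design: ExperimentDesign,
    panel: PanelDefinition,
    kmap: KinaseSubstrateMap,
    effects: list[PlantedEffect],
    noise: NoiseModel,
    seed: int = 0,
    velocity_range: tuple[float, float] = DEFAULT_VELOCITY_RANGE,
    combine_multipliers: str = "product",
) -> ChipSimulation:
    """Simulate kinetic intensities for every panel peptide in every sample.

    ``combine_multipliers`` controls how a peptide targeted by several
    affected kinases combines their multipliers: ``"product"`` (default)
    or ``"max"``.
    """
    if combine_multipliers not in ("product", "max"):
        raise ValueError(f"unknown combine_multipliers {combine_multipliers!r}")
    for eff in effects:
        if eff.kinase_id not in kmap:
            raise KeyError(f"planted effect references unknown kinase {eff.kinase_id!r}")
    rng = _rng(seed, _STREAM_CHIP)
    peptides = list(panel.peptide_ids)
    meta = design.sample_metadata()
    lo, hi = velocity_range
    if not (0 < lo <= hi):
        raise ValueError("velocity_range must be positive and nondecreasing")
    v = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(peptides)))
    baseline = pd.Series(v, index=pd.Index(peptides, name="peptide_id"), name="velocity")

    # per-sample multiplier per peptide
    mult = np.ones((len(peptides), len(meta)))
    pep_index = {p: i for i, p in enumerate(peptides)}
    for j, row in meta.iterrows():
        for eff in effects:
            if (row["genotype"], row["treatment"]) == tuple(eff.condition):
                for p in kmap.substrates(eff.kinase_id):
                    if p in pep_index:
                        i = pep_index[p]
                        if combine_multipliers == "product":
                            mult[i, j] *= eff.activity_multiplier
                        else:
                            mult[i, j] = max(mult[i, j], eff.activity_multiplier)
    eff_v = v[:, None] * mult  # peptide x sample

    times = np.asarray(design.cycle_times_min, dtype=float)
    expos = np.asarray(design.exposures_ms, dtype=float)
    # intensity[p, s, t, e] = background + v_eff * t * e/100
    clean = noise.background_level + eff_v[:, :, None, None] * times[None, None, :, None] * (
        expos[None, None, None, :] / 100.0
    )
    if noise.intensity_cv > 0:
        sigma = np.sqrt(np.log1p(noise.intensity_cv**2))
        eps = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=clean.shape)
        observed = clean * eps
    else:
        observed = clean
    if noise.saturation_ceiling is not None:
        observed = np.minimum(observed, noise.saturation_ceiling)
    observed = np.maximum(observed, 0.0)

    n_p, n_s, n_t, n_e = observed.shape
    kinetics = pd.DataFrame(
        {
            "peptide_id": np.repeat(peptides, n_s * n_t * n_e),
            "sample_id": np.tile(np.repeat(meta["sample_id"].to_numpy(), n_t * n_e), n_p),
            "cycle_time_min": np.tile(np.repeat(times, n_e), n_p * n_s),
            "exposure_ms": np.tile(expos, n_p * n_s * n_t),
            "intensity": observed.ravel(),
        }
    )
    eff_df = pd.DataFrame(eff_v, index=baseline.index, columns=meta["sample_id"].to_numpy())
    return ChipSimulation(kinetics, meta, baseline, eff_df)


def simulate_contrast_tables(
    n_genes: int,
    n_shared_up: int = 0,
    n_shared_down: int = 0,
    n_opposite: int = 0,
    n_unique_each: int = 0,
    effect_log2fc: float = 2.0,
    null_sd: float = 0.25,
    seed: int = 0,
    planted_padj_max: float = 0.01,
    null_padj_min: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired gene contrast tables with planted responder categories.

    Categories planted (truth label in the returned third table):
    ``shared_up``/``shared_down`` (same-direction significant change in
    both contrasts), ``opposite`` (significant with opposite signs),
    ``unique_a``/``unique_b`` (significant in exactly one contrast, sign
    random), ``null`` (no effect). Planted genes draw
    log2fc ~ Normal(+/-effect_log2fc, null_sd) on their significant side
    and padj ~ Uniform(0, planted_padj_max); null sides draw
    log2fc ~ Normal(0, null_sd) and padj ~ Uniform(null_padj_min, 1), so
    the planted labels are exact ground truth by construction (set
    ``null_padj_min=0`` for a full-range uniform null instead).

    Returns ``(table_a, table_b, truth)``; tables have columns
    gene_id, log2fc, padj.
    """
    if effect_log2fc <= 0:
        raise ValueError("effect_log2fc must be > 0")
    n_planted = n_shared_up + n_shared_down + n_opposite + 2 * n_unique_each
    if n_planted > n_genes:
        raise ValueError(
            f"planted category counts sum to {n_planted} > n_genes={n_genes}"
        )
    if min(n_shared_up, n_shared_down, n_opposite, n_unique_each) < 0:
        raise ValueError("category counts must be nonnegative")
    rng = _rng(seed, _STREAM_CONTRAST)
    genes = np.array([f"gene_{i:05d}" for i in range(1, n_genes + 1)])
    perm = rng.permutation(n_genes)
    labels = np.full(n_genes, "null", dtype=object)
    cursor = 0
    for label, count in (
        ("shared_up", n_shared_up),
        ("shared_down", n_shared_down),
        ("opposite", n_opposite),
        ("unique_a", n_unique_each),
        ("unique_b", n_unique_each),
    ):
        labels[perm[cursor : cursor + count]] = label
        cursor += count

    def draw_side(mu: np.ndarray, significant: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lfc = mu + (rng.normal(0.0, null_sd, size=n_genes) if null_sd > 0 else 0.0)
        padj = np.where(
            significant,
            rng.uniform(0.0, planted_padj_max, size=n_genes),
            rng.uniform(null_padj_min, 1.0, size=n_genes),
        )
        return lfc, padj

    sign = rng.choice([-1.0, 1.0], size=n_genes)  # used by opposite/unique categories
    mu_a = np.zeros(n_genes)
    mu_b = np.zeros(n_genes)
    sig_a = np.zeros(n_genes, dtype=bool)
    sig_b = np.zeros(n_genes, dtype=bool)
    for i, lab in enumerate(labels):
        if lab == "shared_up":
            mu_a[i] = mu_b[i] = effect_log2fc
            sig_a[i] = sig_b[i] = True
        elif lab == "shared_down":
            mu_a[i] = mu_b[i] = -effect_log2fc
            sig_a[i] = sig_b[i] = True
        elif lab == "opposite":
            mu_a[i] = sign[i] * effect_log2fc
            mu_b[i] = -sign[i] * effect_log2fc
            sig_a[i] = sig_b[i] = True
        elif lab == "unique_a":
            mu_a[i] = sign[i] * effect_log2fc
            sig_a[i] = True
        elif lab == "unique_b":
            mu_b[i] = sign[i] * effect_log2fc
            sig_b[i] = True
    lfc_a, padj_a = draw_side(mu_a, sig_a)
    lfc_b, padj_b = draw_side(mu_b, sig_b)
    table_a = pd.DataFrame({"gene_id": genes, "log2fc": lfc_a, "padj": padj_a})
    table_b = pd.DataFrame({"gene_id": genes, "log2fc": lfc_b, "padj": padj_b})
    truth = pd.DataFrame({"gene_id": genes, "label": labels})
    return table_a, table_b, truth


def simulate_pathways(
    genes: list[str],
    n_pathways: int = 10,
    genes_per_pathway: tuple[int, int] = (10, 40),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene sets over a universe, GMT-style dict (demo/enrichment fixtures)."""
    rng = _rng(seed, _STREAM_CONTRAST + 1)
    lo, hi = genes_per_pathway
    if hi > len(genes):
        raise ValueError("pathway size exceeds universe")
    out: dict[str, list[str]] = {}
    for i in range(1, n_pathways + 1):
        n = int(rng.integers(lo, hi + 1))
        out[f"PATH_{i:03d}"] = sorted(rng.choice(genes, size=n, replace=False))
    return out
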