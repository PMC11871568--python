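"""Standard seeded evaluation experiments on the synthetic benchmark.

These are the package's calibration and recovery studies, each run at the
benchmark's reference conditions:

* ``null_calibration`` — no planted effects, 20 kinases on the 144-peptide
  STK panel, triplicates, 10% intensity CV: the upstream-kinase statistics
  should sit at their null values (mean delta confidence near 1, few
  |z| > 1.96).
* ``planted_recovery`` — one kinase with 8 exclusive substrates doubled in
  activity in the knockout+TGFb condition, 15% intensity CV: that kinase
  should attain the top |MEOW| score in nearly every seeded run.
* ``partition_roundtrip`` — noiseless planted contrast tables: the
  dual-contrast partition must recover the planted category counts exactly.

Runs simulate only the two sample groups the scored comparison uses
(knockout vs. control, TGFb-treated, triplicate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ExperimentDesign, NoiseModel, PlantedEffect
from .differential import GroupComparison, fold_change, groups_from_metadata, select_differential
from .kinase import KinaseSubstrateMap, analyze_comparison
from .panels import PanelDefinition, default_panel
from .signal import extract_signals
from .synthetic import generate_kinase_map, simulate_chip_run, simulate_contrast_tables
from .contrast import partition_genes

CALIBRATION_DESIGN = ExperimentDesign(
    genotypes=("Scramble", "INSR_KO"),
    treatments=("TGFb",),
    replicates_per_cell=3,
)


def _run_comparison(
    panel: PanelDefinition,
    kmap: KinaseSubstrateMap,
    effects: list[PlantedEffect],
    cv: float,
    seed: int,
    iterations: int = 2000,
) -> pd.DataFrame:
    """Simulate a chip run and score the KO-TGFb vs Scramble-TGFb comparison."""
    sim = simulate_chip_run(
        CALIBRATION_DESIGN, panel, kmap, effects, NoiseModel(intensity_cv=cv), seed=seed
    )
    signals = extract_signals(sim.kinetics)
    cmp = GroupComparison(
        name="KO_vs_Scramble_TGFb",
        group_a=groups_from_metadata(sim.metadata, "INSR_KO", "TGFb"),
        group_b=groups_from_metadata(sim.metadata, "Scramble", "TGFb"),
    )
    fc = fold_change(signals, cmp)
    diff = select_differential(fc, name=cmp.name)
    return analyze_comparison(diff, fc, kmap, iterations=iterations, seed=seed + 1)


def null_calibration(
    seeds: list[int],
    n_kinases: int = 20,
    cv: float = 0.1,
    iterations: int = 2000,
) -> dict[str, float]:
    """No-effect runs: pooled mean delta confidence and tail fraction of |z|.

    Returns mean delta confidence over all finite per-kinase values across
    seeds, the fraction of finite |z| exceeding 1.96, and the counts.
    """
    panel = default_panel("STK")
    deltas: list[float] = []
    zs: list[float] = []
    for seed in seeds:
        kmap = generate_kinase_map(n_kinases, panel, (5, 15), 0.3, seed=seed)
        stats = _run_comparison(panel, kmap, [], cv, seed, iterations=iterations)
        deltas.extend(stats["delta_confidence"].to_numpy(dtype=float))
        zs.extend(stats["z"].to_numpy(dtype=float))
    d = np.array([x for x in deltas if np.isfinite(x)])
    z = np.array([x for x in zs if np.isfinite(x)])
    return {
        "mean_delta_confidence": float(d.mean()) if d.size else float("nan"),
        "frac_abs_z_gt_1p96": float((np.abs(z) > 1.96).mean()) if z.size else float("nan"),
        "n_delta": int(d.size),
        "n_z": int(z.size),
    }


def make_planted_map(
    panel: PanelDefinition,
    n_exclusive: int = 8,
    n_decoys: int = 19,
    seed: int = 0,
) -> tuple[KinaseSubstrateMap, str]:
    """Substrate map with one kinase owning ``n_exclusive`` dedicated peptides.

    Decoy kinases draw their substrates only from the remaining peptides,
    so the planted kinase's substrates are exclusive by construction.
    """
    planted = "KIN_PLANTED"
    exclusive = list(panel.peptide_ids[:n_exclusive])
    rest = PanelDefinition("rest", tuple(panel.peptide_ids[n_exclusive:]))
    decoys = generate_kinase_map(n_decoys, rest, (5, 15), 0.3, seed=seed)
    pairs = [(planted, p) for p in exclusive] + decoys.pairs
    return KinaseSubstrateMap(pairs), planted


def planted_recovery(
    seeds: list[int],
    multiplier: float = 2.0,
    n_exclusive: int = 8,
    cv: float = 0.15,
    iterations: int = 2000,
) -> dict[str, float]:
    """Fraction of seeded runs where the planted kinase tops the |MEOW| ranking."""
    panel = default_panel("STK")
    wins = 0
    for seed in seeds:
        kmap, planted = make_planted_map(panel, n_exclusive=n_exclusive, seed=seed)
        effects = [PlantedEffect(planted, ("INSR_KO", "TGFb"), multiplier)]
        stats = _run_comparison(panel, kmap, effects, cv, seed, iterations=iterations)
        ranked = stats.assign(abs_meow=stats["meow"].abs()).sort_values(
            "abs_meow", ascending=False
        )
        if len(ranked) and ranked.iloc[0]["kinase_id"] == planted:
            wins += 1
    return {"n_runs": len(seeds), "n_top_ranked": wins, "top_rank_rate": wins / len(seeds)}


def partition_roundtrip(n_configs: int = 50, seed: int = 0) -> dict[str, float]:
    """Noiseless planted contrast tables across randomized configurations.

    For each configuration, random planted category counts are drawn, the
    tables are generated with zero log2fc noise, and the recovered
    partition counts are compared with the planted truth.
    """
    rng = np.random.default_rng(seed)
    exact = 0
    for i in range(n_configs):
        n_genes = int(rng.integers(200, 1001))
        counts = {
            "n_shared_up": int(rng.integers(0, 30)),
            "n_shared_down": int(rng.integers(0, 30)),
            "n_opposite": int(rng.integers(0, 10)),
            "n_unique_each": int(rng.integers(0, 20)),
        }
        a, b, truth = simulate_contrast_tables(
            n_genes=n_genes, effect_log2fc=2.0, null_sd=0.0,
            seed=int(rng.integers(0, 2**31 - 1)), **counts,
        )
        part = partition_genes(a, b)
        got = part.counts()
        ok = (
            got["shared_up"] == counts["n_shared_up"]
            and got["shared_down"] == counts["n_shared_down"]
            and got["opposite"] == counts["n_opposite"]
            and got["unique_to_a"] == counts["n_unique_each"]
            and got["unique_to_b"] == counts["n_unique_each"]
        )
        # set-level check too: recovered members must equal the planted labels
        lab = truth.set_index("gene_id")["label"]
        ok = ok and set(part.shared_up) == set(lab.index[lab == "shared_up"])
        ok = ok and set(part.opposite) == set(lab.index[lab == "opposite"])
        exact += bool(ok)
    return {"n_configs": n_configs, "n_exact": exact, "exact_rate": exact / n_configs}
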