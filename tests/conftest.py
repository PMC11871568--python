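import numpy as np
import pandas as pd
import pytest

import kinomeflow as kf


@pytest.fixture(scope="session")
def tiny_panel() -> kf.PanelDefinition:
    return kf.make_panel("P", 10)


@pytest.fixture(scope="session")
def small_design() -> kf.ExperimentDesign:
    """Two genotypes, one treatment, triplicate — the scored comparison only."""
    return kf.ExperimentDesign(
        genotypes=("Scramble", "INSR_KO"), treatments=("TGFb",), replicates_per_cell=3
    )


@pytest.fixture(scope="session")
def noiseless_run(small_design, tiny_panel):
    """A noiseless chip run with one kinase doubled in the knockout."""
    kmap = kf.KinaseSubstrateMap(
        [("K1", p) for p in tiny_panel.peptide_ids[:4]]
        + [("K2", p) for p in tiny_panel.peptide_ids[4:8]]
    )
    effects = [kf.PlantedEffect("K1", ("INSR_KO", "TGFb"), 2.0)]
    sim = kf.simulate_chip_run(
        small_design, tiny_panel, kmap, effects, kf.NoiseModel(intensity_cv=0.0), seed=11
    )
    return sim, kmap


@pytest.fixture(scope="session")
def noiseless_signals(noiseless_run):
    sim, kmap = noiseless_run
    return kf.extract_signals(sim.kinetics), sim, kmap


def make_signal_table(values: dict[tuple[str, str], float], qc: dict[tuple[str, str], bool] | None = None) -> pd.DataFrame:
    """Hand-built signal table from {(peptide, sample): signal}."""
    rows = []
    for (pep, smp), v in values.items():
        rows.append(
            {
                "peptide_id": pep,
                "sample_id": smp,
                "slope": v,
                "intercept": 0.0,
                "r_squared": 1.0,
                "n_points": 13,
                "signal": v,
                "qc_pass": True if qc is None else qc[(pep, smp)],
            }
        )
    return pd.DataFrame(rows)
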