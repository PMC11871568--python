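"""Experiment-design and noise-model descriptions for simulated chip runs.

The default design mirrors a two-genotype (Scramble control vs. receptor
knockout) by three-treatment (Vehicle, Insulin, TGFb) layout run in
triplicate, with the kinetic read schedule of the instrument: one image
every 5 minutes for an hour, at four CCD exposure times (10/20/50/100 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_CYCLE_TIMES_MIN: tuple[float, ...] = tuple(float(t) for t in range(0, 65, 5))
DEFAULT_EXPOSURES_MS: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial sample layout plus the kinetic acquisition schedule."""

    genotypes: tuple[str, ...] = ("Scramble", "INSR_KO")
    treatments: tuple[str, ...] = ("Vehicle", "Insulin", "TGFb")
    replicates_per_cell: int = 3
    cycle_times_min: tuple[float, ...] = DEFAULT_CYCLE_TIMES_MIN
    exposures_ms: tuple[float, ...] = DEFAULT_EXPOSURES_MS

    def __post_init__(self) -> None:
        if len(self.cycle_times_min) < 2:
            raise ValueError("need at least 2 cycle times")
        if list(self.cycle_times_min) != sorted(set(self.cycle_times_min)):
            raise ValueError("cycle_times_min must be strictly increasing")
        if len(self.exposures_ms) < 1:
            raise ValueError("need at least 1 exposure time")
        if list(self.exposures_ms) != sorted(set(self.exposures_ms)):
            raise ValueError("exposures_ms must be strictly increasing")
        if any(e <= 0 for e in self.exposures_ms):
            raise ValueError("exposure times must be positive")
        if any(t < 0 for t in self.cycle_times_min):
            raise ValueError("cycle times must be nonnegative")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        if not self.genotypes or not self.treatments:
            raise ValueError("genotypes and treatments must be non-empty")

    @property
    def n_samples(self) -> int:
        return len(self.genotypes) * len(self.treatments) * self.replicates_per_cell

    def sample_metadata(self) -> pd.DataFrame:
        """One row per sample: sample_id, genotype, treatment, replicate."""
        rows = [
            {
                "sample_id": f"{g}_{t}_r{r}",
                "genotype": g,
                "treatment": t,
                "replicate": r,
            }
            for g in self.genotypes
            for t in self.treatments
            for r in range(1, self.replicates_per_cell + 1)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth activity change for one kinase in one condition.

    All substrates of ``kinase_id`` have their phosphorylation velocity
    multiplied by ``activity_multiplier`` in every sample whose
    (genotype, treatment) matches ``condition``. 1.0 means no effect.
    """

    kinase_id: str
    condition: tuple[str, str]
    activity_multiplier: float

    def __post_init__(self) -> None:
        if self.activity_multiplier <= 0:
            raise ValueError("activity_multiplier must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for simulated intensities.

    intensity_cv
        fractional coefficient of variation of the multiplicative
        lognormal noise applied to each observed intensity (0 = noiseless).
    background_level
        additive constant intensity present at every exposure,
        emulating non-specific fluorescence.
    saturation_ceiling
        optional detector ceiling; observed intensities are clipped
        here after noise. ``None`` disables clipping.
    """

    intensity_cv: float = 0.1
    background_level: float = 50.0
    saturation_ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.saturation_ceiling is not None and self.saturation_ceiling <= self.background_level:
            raise ValueError("saturation_ceiling must exceed background_level")
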