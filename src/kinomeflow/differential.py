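"""Per-peptide fold changes between sample groups and differential selection.

Fold change is the ratio of group-averaged slope signals
(ratio of means across replicates). A peptide is differentially
phosphorylated when FC >= 1.30 or FC <= 0.70, both bounds inclusive.
A peptide enters a comparison only if it passed the R^2 quality filter in
EVERY sample of the comparison, so both terms of the ratio are valid; the
set of such peptides is the comparison's background, the universe the
sampling null draws from.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

FC_UP_DEFAULT = 1.30
FC_DOWN_DEFAULT = 0.70


@dataclass(frozen=True)
class GroupComparison:
    """Named two-group comparison; group_a is the numerator of the ratio."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("both groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("groups must be disjoint")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.group_a) + tuple(self.group_b)

    def swapped(self) -> "GroupComparison":
        return GroupComparison(self.name + "_swapped", self.group_b, self.group_a)


@dataclass(frozen=True)
class DifferentialSet:
    """Up/down differential peptides plus the QC background they came from."""

    name: str
    up: frozenset[str]
    down: frozenset[str]
    background: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")
        if not (self.up | self.down) <= self.background:
            raise ValueError("differential peptides must lie in the background")

    @property
    def differential(self) -> frozenset[str]:
        return self.up | self.down


def groups_from_metadata(metadata: pd.DataFrame, genotype: str, treatment: str) -> tuple[str, ...]:
    """Sample ids of one (genotype, treatment) cell, ordered by replicate."""
    sel = metadata[(metadata["genotype"] == genotype) & (metadata["treatment"] == treatment)]
    if sel.empty:
        raise KeyError(f"no samples with genotype={genotype!r} treatment={treatment!r}")
    return tuple(sel.sort_values("replicate")["sample_id"])


def comparison_background(signals: pd.DataFrame, cmp: GroupComparison) -> frozenset[str]:
    """Peptides that pass QC in every sample of the comparison."""
    sub = signals[signals["sample_id"].isin(cmp.samples)]
    missing = set(cmp.samples) - set(sub["sample_id"])
    if missing:
        raise KeyError(f"samples absent from signal table: {sorted(missing)}")
    qc = sub.pivot(index="peptide_id", columns="sample_id", values="qc_pass")
    qc = qc.reindex(columns=list(cmp.samples))
    ok = qc.notna().all(axis=1) & qc.fillna(False).astype(bool).all(axis=1)
    return frozenset(qc.index[ok])


def fold_change(
    signals: pd.DataFrame,
    cmp: GroupComparison,
    method: str = "ratio_of_means",
) -> pd.DataFrame:
    """Per-peptide fold change ``mean(group_a signal) / mean(group_b signal)``.

    Only peptides in the comparison background (QC pass in all samples of
    both groups) are reported. ``method="mean_of_ratios"`` instead averages
    per-replicate-pair ratios (requires equal group sizes); the default
    ratio-of-means is stable for unpaired replicates.
    """
    if method not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown method {method!r}")
    eligible = comparison_background(signals, cmp)
    empty = pd.DataFrame(columns=["peptide_id", "fc", "log2fc", "n_a", "n_b"])
    if not eligible:
        return empty
    sub = signals[signals["sample_id"].isin(cmp.samples) & signals["peptide_id"].isin(eligible)]
    wide = sub.pivot(index="peptide_id", columns="sample_id", values="signal")
    a = wide[list(cmp.group_a)].to_numpy(dtype=float)
    b = wide[list(cmp.group_b)].to_numpy(dtype=float)
    if method == "ratio_of_means":
        fc = a.mean(axis=1) / b.mean(axis=1)
    else:
        if a.shape[1] != b.shape[1]:
            raise ValueError("mean_of_ratios requires equal group sizes")
        fc = (a / b).mean(axis=1)
    out = pd.DataFrame(
        {
            "peptide_id": wide.index,
            "fc": fc,
            "log2fc": np.log2(fc),
            "n_a": len(cmp.group_a),
            "n_b": len(cmp.group_b),
        }
    ).reset_index(drop=True)
    return out.sort_values("peptide_id", ignore_index=True)


def select_differential(
    records: pd.DataFrame,
    name: str = "comparison",
    up_threshold: float = FC_UP_DEFAULT,
    down_threshold: float = FC_DOWN_DEFAULT,
) -> DifferentialSet:
    """Apply the inclusive fold-change thresholds to a fold-change table."""
    if not (up_threshold > 1 > down_threshold > 0):
        raise ValueError("thresholds must satisfy up > 1 > down > 0")
    fc = records.set_index("peptide_id")["fc"]
    up = frozenset(fc.index[fc >= up_threshold])
    down = frozenset(fc.index[fc <= down_threshold])
    return DifferentialSet(name=name, up=up, down=down, background=frozenset(fc.index))


def percent_change(mean_log2fc: float) -> float:
    """Signed percent change implied by a mean log2 fold change: (2**x - 1) * 100."""
    if not np.isfinite(mean_log2fc):
        raise ValueError("mean_log2fc must be finite")
    return (2.0 ** mean_log2fc - 1.0) * 100.0
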