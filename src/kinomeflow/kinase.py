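"""Upstream-kinase inference from a differential phosphopeptide set.

The question this module answers: given the set of reporter peptides whose
phosphorylation changed between two conditions, which upstream kinases are
plausibly responsible? Each kinase is scored by how many of its annotated
substrate peptides fall in the differential set ("experimental hits"),
compared against a random-sampling null: equally sized peptide sets drawn
uniformly without replacement from the comparison's QC-passing background.

Per kinase we report

* ``z`` — (observed − mean_null) / sd_null, the standardized hit excess;
* ``delta_confidence`` — observed / mean_null, the fold excess of hits over
  chance (2000 sampling iterations by default);
* ``mean_substrate_log2fc`` — the signed average log2 fold change across
  ALL of the kinase's QC-passing substrates in the comparison, capturing
  the direction of the activity change;
* ``meow`` — mean_substrate_log2fc × delta_confidence, a single
  direction-aware enrichment score per kinase ("measurements extensively
  of winner").

The exact hypergeometric moments of the null are available as an oracle
(`exhaustive_null`), and small backgrounds can be enumerated outright.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import DifferentialSet

DEFAULT_ITERATIONS = 2000
DEFAULT_MIN_SUBSTRATES = 3

#: flags attached to KinaseStatRecord
FLAG_OK = "ok"
FLAG_UNSTABLE_Z = "unstable_z"            # sd_null == 0 but observed != mean_null
FLAG_DEGENERATE_NULL = "degenerate_null"  # mean_null == 0 and observed == 0 (empty diff set etc.)
FLAG_UNDEFINED_DELTA = "undefined_delta"  # mean_null == 0 with observed > 0
FLAG_NO_SUBSTRATE_FC = "no_substrate_fc"  # no QC-passing substrate fold changes


class KinaseSubstrateMap:
    """Many-to-many kinase → reporter-peptide substrate annotation."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        seen: set[tuple[str, str]] = set()
        ordered: list[tuple[str, str]] = []
        for kin, pep in pairs:
            pair = (str(kin), str(pep))
            if pair in seen:
                raise ValueError(f"duplicate kinase-peptide pair {pair}")
            seen.add(pair)
            ordered.append(pair)
        self._pairs = ordered
        self._by_kinase: dict[str, frozenset[str]] = {}
        tmp: dict[str, set[str]] = {}
        for kin, pep in ordered:
            tmp.setdefault(kin, set()).add(pep)
        self._by_kinase = {k: frozenset(v) for k, v in tmp.items()}

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self._pairs)

    @property
    def kinases(self) -> list[str]:
        return sorted(self._by_kinase)

    def substrates(self, kinase_id: str) -> frozenset[str]:
        if kinase_id not in self._by_kinase:
            raise KeyError(f"unknown kinase {kinase_id!r}")
        return self._by_kinase[kinase_id]

    def __contains__(self, kinase_id: object) -> bool:
        return kinase_id in self._by_kinase

    def __len__(self) -> int:
        return len(self._by_kinase)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._pairs, columns=["kinase_id", "peptide_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KinaseSubstrateMap":
        return cls(zip(df["kinase_id"].astype(str), df["peptide_id"].astype(str)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KinaseSubstrateMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class NullDistribution:
    """Monte-Carlo null of per-kinase hit counts under random peptide draws."""

    kinase_id: str
    iterations: int
    hit_counts: np.ndarray
    mean_hits: float
    sd_hits: float


@dataclass
class KinaseStatRecord:
    kinase_id: str
    observed_hits: int
    mean_null: float
    sd_null: float
    z: float
    delta_confidence: float
    mean_substrate_log2fc: float
    meow: float
    n_substrates_in_background: int
    flag: str = FLAG_OK


def observed_hits(kinase_id: str, diff: DifferentialSet, kmap: KinaseSubstrateMap) -> int:
    """Number of the kinase's substrates in the differential (up ∪ down) set."""
    return len(kmap.substrates(kinase_id) & diff.differential)


def sampling_null(
    kinase_id: str,
    n_diff: int,
    kmap: KinaseSubstrateMap,
    background: Iterable[str],
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> NullDistribution:
    """Random-sampling null for one kinase.

    Each iteration draws ``n_diff`` peptides uniformly without replacement
    from ``background`` and counts how many are substrates of the kinase.
    Deterministic given ``seed``.
    """
    bg = sorted(set(background))
    n_bg = len(bg)
    if n_diff > n_bg:
        raise ValueError(f"n_diff={n_diff} exceeds background size {n_bg}")
    member = np.array([p in kmap.substrates(kinase_id) for p in bg], dtype=bool)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n_diff == 0 or n_bg == 0:
        hits = np.zeros(iterations, dtype=np.int64)
    else:
        # uniform draws without replacement: first n_diff columns of random orderings
        order = np.argsort(rng.random((iterations, n_bg)), axis=1)[:, :n_diff]
        hits = member[order].sum(axis=1)
    sd = float(hits.std(ddof=1)) if iterations > 1 else 0.0
    return NullDistribution(kinase_id, iterations, hits, float(hits.mean()), sd)


def exhaustive_null(
    kinase_id: str,
    n_diff: int,
    kmap: KinaseSubstrateMap,
    background: Iterable[str],
) -> tuple[float, float]:
    """Exact null mean and variance of the hit count (hypergeometric moments).

    For K substrates in a background of N peptides with n drawn:
    mean = n*K/N, var = n*(K/N)*(1-K/N)*(N-n)/(N-1).
    """
    bg = set(background)
    n_bg = len(bg)
    if n_diff > n_bg:
        raise ValueError(f"n_diff={n_diff} exceeds background size {n_bg}")
    k_in_bg = len(kmap.substrates(kinase_id) & bg)
    if n_bg == 0 or k_in_bg == 0 or n_diff == 0:
        return 0.0, 0.0
    p = k_in_bg / n_bg
    mean = n_diff * p
    var = 0.0 if n_bg == 1 else n_diff * p * (1 - p) * (n_bg - n_diff) / (n_bg - 1)
    return mean, var


def enumerate_null(
    kinase_id: str,
    n_diff: int,
    kmap: KinaseSubstrateMap,
    background: Iterable[str],
) -> tuple[float, float]:
    """Brute-force null moments by enumerating every C(N, n) subset (tiny N only)."""
    bg = sorted(set(background))
    subs = kmap.substrates(kinase_id)
    counts = [len(subs & set(c)) for c in itertools.combinations(bg, n_diff)]
    arr = np.array(counts, dtype=float)
    return float(arr.mean()), float(arr.var())


def kinase_statistics(
    observed: int,
    null: NullDistribution,
    substrate_log2fcs: Sequence[float],
    n_substrates_in_background: int | None = None,
) -> KinaseStatRecord:
    """Combine observed hits, the sampling null, and substrate fold changes.

    Degenerate cases are flagged, never silently divided through:
    sd_null==0 gives z=0 when observed equals the null mean and a signed
    infinity sentinel otherwise; mean_null==0 gives delta_confidence 1.0
    when observed is also 0 (the kinase sits exactly at its trivially empty
    null) and NaN when observed > 0.
    """
    flag = FLAG_OK
    mean, sd = null.mean_hits, null.sd_hits
    if sd == 0:
        if observed == mean:
            z = 0.0
        else:
            z = math.inf if observed > mean else -math.inf
            flag = FLAG_UNSTABLE_Z
    else:
        z = (observed - mean) / sd
    if mean == 0:
        if observed == 0:
            delta = 1.0
            flag = FLAG_DEGENERATE_NULL if flag == FLAG_OK else flag
        else:
            delta = math.nan
            flag = FLAG_UNDEFINED_DELTA
    else:
        delta = observed / mean
    if len(substrate_log2fcs) == 0:
        mean_lfc = math.nan
        flag = FLAG_NO_SUBSTRATE_FC
    else:
        mean_lfc = float(np.mean(substrate_log2fcs))
    meow = mean_lfc * delta
    return KinaseStatRecord(
        kinase_id=null.kinase_id,
        observed_hits=int(observed),
        mean_null=mean,
        sd_null=sd,
        z=z,
        delta_confidence=delta,
        mean_substrate_log2fc=mean_lfc,
        meow=meow,
        n_substrates_in_background=(
            len(substrate_log2fcs) if n_substrates_in_background is None else n_substrates_in_background
        ),
        flag=flag,
    )


def analyze_comparison(
    diff: DifferentialSet,
    fold_changes: pd.DataFrame,
    kmap: KinaseSubstrateMap,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    min_substrates: int = DEFAULT_MIN_SUBSTRATES,
) -> pd.DataFrame:
    """Score every retained kinase for one comparison.

    A kinase is retained when it has at least ``min_substrates`` substrates
    in the comparison's QC-passing background. One set of ``iterations``
    random peptide draws is shared across kinases (each kinase's marginal
    null is unchanged; this mirrors how sampling analyzers batch the null).

    Parameters
    ----------
    diff : differential set (up/down/background peptides) for the comparison
    fold_changes : per-peptide table with columns peptide_id, log2fc
    """
    bg = sorted(diff.background)
    n_bg = len(bg)
    diff_set = diff.differential
    n_diff = len(diff_set)
    lfc = fold_changes.set_index("peptide_id")["log2fc"]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n_diff > 0 and n_bg > 0:
        order = np.argsort(rng.random((iterations, n_bg)), axis=1)[:, :n_diff]
    else:
        order = None

    bg_index = {p: i for i, p in enumerate(bg)}
    records: list[KinaseStatRecord] = []
    for kin in kmap.kinases:
        subs_in_bg = kmap.substrates(kin) & set(bg)
        if len(subs_in_bg) < min_substrates:
            continue
        member = np.zeros(n_bg, dtype=bool)
        for p in subs_in_bg:
            member[bg_index[p]] = True
        if order is None:
            hits = np.zeros(iterations, dtype=np.int64)
        else:
            hits = member[order].sum(axis=1)
        sd = float(hits.std(ddof=1)) if iterations > 1 else 0.0
        null = NullDistribution(kin, iterations, hits, float(hits.mean()), sd)
        obs = len(subs_in_bg & diff_set)
        sub_lfcs = lfc.reindex(sorted(subs_in_bg)).dropna().to_numpy()
        records.append(
            kinase_statistics(obs, null, sub_lfcs, n_substrates_in_background=len(subs_in_bg))
        )
    return records_to_frame(records)


def records_to_frame(records: Sequence[KinaseStatRecord]) -> pd.DataFrame:
    cols = [
        "kinase_id",
        "observed_hits",
        "mean_null",
        "sd_null",
        "z",
        "delta_confidence",
        "mean_substrate_log2fc",
        "meow",
        "n_substrates_in_background",
        "flag",
    ]
    return pd.DataFrame([vars(r) for r in records], columns=cols)


def summarize_kinome(
    stats: pd.DataFrame,
    families: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Aggregate kinase statistics across comparisons/chips into node attributes.

    Per kinase: ``color_value`` is the median z ("kinase statistic") and
    ``size_value`` the mean |meow| ("final score"), the two attributes a
    kinome-tree renderer maps to node color and node size. Non-finite z or
    meow values (flagged degenerate records) are excluded from the medians
    and means.
    """
    if stats.empty:
        return pd.DataFrame(
            columns=["kinase_id", "family", "median_kinase_statistic", "mean_final_score",
                     "n_records", "size_value", "color_value"]
        )
    rows = []
    for kin, grp in stats.groupby("kinase_id", sort=True):
        z = grp["z"].to_numpy(dtype=float)
        z = z[np.isfinite(z)]
        meow = grp["meow"].to_numpy(dtype=float)
        meow = meow[np.isfinite(meow)]
        rows.append(
            {
                "kinase_id": kin,
                "family": (families or {}).get(kin, ""),
                "median_kinase_statistic": float(np.median(z)) if z.size else math.nan,
                "mean_final_score": float(np.mean(np.abs(meow))) if meow.size else math.nan,
                "n_records": len(grp),
            }
        )
    out = pd.DataFrame(rows)
    out["size_value"] = out["mean_final_score"]
    out["color_value"] = out["median_kinase_statistic"]
    return out
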