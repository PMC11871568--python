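"""Dual-contrast transcriptome logic: gene filtering, Venn partition,
receptor-dependence ranking, and local pathway enrichment.

The analysis consumes two per-gene differential tables — the
TGFb-vs-vehicle contrast in knockout cells (contrast *b*) and in control
cells (contrast *a*) — and asks which transcriptional responses depend on
the receptor:

* genes significant (padj < .05, strict) in both contrasts partition into
  shared-up, shared-down and oppositely regulated;
* genes significant in exactly one contrast are condition-specific;
* a per-gene dependence score log2FC_b − log2FC_a ranks genes by how much
  the knockout changes their response; the top and bottom 100 feed
  pathway enrichment;
* enrichment is a local hypergeometric over-representation test against a
  user-supplied GMT collection, BH-adjusted, summarized by an
  "amalgamated enrichment score" AES = n_overlap * (−log10 padj) — a
  monotone combination of overlap size and significance (the combiner is
  pluggable; this instantiation is one documented choice).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

PADJ_CUTOFF_DEFAULT = 0.05
TOP_N_DEFAULT = 100
MIN_FPM_DEFAULT = 5.0
MIN_FRACTION_DEFAULT = 0.75


@dataclass(frozen=True)
class GenePartition:
    """Disjoint classification of significant genes across two contrasts."""

    shared_up: frozenset[str]
    shared_down: frozenset[str]
    opposite: frozenset[str]
    unique_to_a: frozenset[str]
    unique_to_b: frozenset[str]
    shared_flat: frozenset[str]  # significant in both, log2fc exactly 0 in at least one

    @property
    def shared_total(self) -> int:
        return (
            len(self.shared_up)
            + len(self.shared_down)
            + len(self.opposite)
            + len(self.shared_flat)
        )

    def counts(self) -> dict[str, int]:
        return {
            "shared_up": len(self.shared_up),
            "shared_down": len(self.shared_down),
            "opposite": len(self.opposite),
            "unique_to_a": len(self.unique_to_a),
            "unique_to_b": len(self.unique_to_b),
            "shared_flat": len(self.shared_flat),
            "shared_total": self.shared_total,
        }

    def to_dict(self) -> dict[str, list[str]]:
        return {
            name: sorted(getattr(self, name))
            for name in (
                "shared_up",
                "shared_down",
                "opposite",
                "unique_to_a",
                "unique_to_b",
                "shared_flat",
            )
        }


def filter_genes(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    min_fpm: float = MIN_FPM_DEFAULT,
    min_fraction: float = MIN_FRACTION_DEFAULT,
) -> list[str]:
    """Fragments-per-million expression filter.

    Keeps a gene when its FPM ((count / library_size) * 1e6) is at least
    ``min_fpm`` (inclusive) in at least ``ceil(min_fraction * n_samples)``
    samples. ``counts`` is genes x samples; library sizes default to the
    column sums.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    lib = counts.sum(axis=0) if library_sizes is None else library_sizes.reindex(counts.columns)
    if (lib <= 0).any() or lib.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    fpm = counts.div(lib, axis=1) * 1e6
    needed = math.ceil(min_fraction * counts.shape[1])
    keep = (fpm >= min_fpm).sum(axis=1) >= needed
    return list(counts.index[keep])


def _check_table(df: pd.DataFrame, name: str) -> pd.DataFrame:
    if df["gene_id"].duplicated().any():
        raise ValueError(f"duplicate gene_ids in contrast table {name}")
    bad = ~df["padj"].between(0, 1) & df["padj"].notna()
    if bad.any():
        raise ValueError(f"padj outside [0, 1] in contrast table {name}")
    return df.set_index("gene_id")


def partition_genes(
    a: pd.DataFrame,
    b: pd.DataFrame,
    padj_cutoff: float = PADJ_CUTOFF_DEFAULT,
) -> GenePartition:
    """Venn partition of significant genes across two contrast tables.

    Significance is strict padj < cutoff. Shared genes split by the signs
    of their two log2 fold changes; a shared gene with a log2fc of exactly
    0 on either side falls in the degenerate ``shared_flat`` bucket.
    """
    ta = _check_table(a, "a")
    tb = _check_table(b, "b")
    sig_a = set(ta.index[ta["padj"] < padj_cutoff])
    sig_b = set(tb.index[tb["padj"] < padj_cutoff])
    shared = sig_a & sig_b
    lfc_a = ta["log2fc"]
    lfc_b = tb["log2fc"]
    up, down, opp, flat = set(), set(), set(), set()
    for g in shared:
        xa, xb = lfc_a[g], lfc_b[g]
        if xa > 0 and xb > 0:
            up.add(g)
        elif xa < 0 and xb < 0:
            down.add(g)
        elif xa == 0 or xb == 0:
            flat.add(g)
        else:
            opp.add(g)
    return GenePartition(
        shared_up=frozenset(up),
        shared_down=frozenset(down),
        opposite=frozenset(opp),
        unique_to_a=frozenset(sig_a - sig_b),
        unique_to_b=frozenset(sig_b - sig_a),
        shared_flat=frozenset(flat),
    )


@dataclass(frozen=True)
class DependenceRanking:
    """Per-gene dependence scores with the top/bottom selections."""

    scores: pd.Series        # index gene_id, value log2fc_b - log2fc_a
    top: list[str]           # highest scores (knockout gains response)
    bottom: list[str]        # lowest scores


def dependence_scores(
    a: pd.DataFrame,
    b: pd.DataFrame,
    top_n: int = TOP_N_DEFAULT,
) -> DependenceRanking:
    """Receptor-dependence score per gene: log2FC in contrast b minus contrast a.

    Computed over the genes present in both tables. Returns the ``top_n``
    highest- and lowest-scoring genes; ties break lexicographically by
    gene_id (deterministic). If ``top_n`` exceeds half the shared
    universe, a warning is raised and the lists are truncated so they
    cannot overlap.
    """
    ta = _check_table(a, "a")
    tb = _check_table(b, "b")
    common = ta.index.intersection(tb.index).sort_values()
    scores = (tb.loc[common, "log2fc"] - ta.loc[common, "log2fc"]).rename("dependence_score")
    n = len(scores)
    eff_n = top_n
    if top_n > n // 2:
        warnings.warn(
            f"top_n={top_n} exceeds half the {n}-gene universe; truncating to {n // 2}",
            stacklevel=2,
        )
        eff_n = n // 2
    ranked = scores.reset_index().sort_values(
        ["dependence_score", "gene_id"], ascending=[False, True]
    )
    top = ranked["gene_id"].head(eff_n).tolist()
    ranked_low = scores.reset_index().sort_values(
        ["dependence_score", "gene_id"], ascending=[True, True]
    )
    bottom = ranked_low["gene_id"].head(eff_n).tolist()
    return DependenceRanking(scores=scores, top=top, bottom=bottom)


def default_aes(n_overlap: np.ndarray, padj: np.ndarray) -> np.ndarray:
    """AES = n_overlap * (−log10 padj); padj floored at 1e-300 to stay finite."""
    return n_overlap * (-np.log10(np.maximum(padj, 1e-300))) + 0.0


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into a name -> member-genes mapping."""
    from gseapy import read_gmt as _read_gmt

    return {k: list(v) for k, v in _read_gmt(str(path)).items()}


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def enrich(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    aes_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = default_aes,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in each pathway.

    p-value is the upper tail P(X >= n_overlap) for drawing |query| genes
    from a universe of N genes containing K pathway members; BH adjustment
    across the tested pathways; AES combines overlap size and adjusted
    significance. Results sort by AES descending, then overlap, then name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    q = set(query)
    if not q <= uni:
        raise ValueError("query genes must be a subset of the universe")
    names, ks, ns_path = [], [], []
    for name, genes in gene_sets.items():
        members = set(genes) & uni
        names.append(name)
        ns_path.append(len(members))
        ks.append(len(members & q))
    n_overlap = np.array(ks)
    path_size = np.array(ns_path)
    N, n_query = len(uni), len(q)
    pvals = hypergeom.sf(n_overlap - 1, N, path_size, n_query)
    pvals = np.clip(pvals, 0.0, 1.0)
    padj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    aes = aes_fn(n_overlap, padj)
    out = pd.DataFrame(
        {
            "pathway_id": names,
            "pathway_size": path_size,
            "n_overlap": n_overlap,
            "p_value": pvals,
            "padj": padj,
            "aes": aes,
        }
    )
    return out.sort_values(
        ["aes", "n_overlap", "pathway_id"], ascending=[False, False, True], ignore_index=True
    )
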