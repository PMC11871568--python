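"""Reporter-peptide panel definitions.

A peptide microarray panel is an ordered collection of reporter peptide
substrates. The two default panels mirror the commercial chip layouts used
for kinase-activity profiling: a serine–threonine kinase (STK) chip with
144 reporter peptides and a protein-tyrosine kinase (PTK) chip with 196.
Peptide identifiers here are synthetic placeholders (``STK_001`` ...);
no proprietary peptide sequences or annotations are shipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STK_PANEL_SIZE = 144
PTK_PANEL_SIZE = 196


@dataclass(frozen=True)
class PanelDefinition:
    """An ordered set of unique reporter peptide identifiers."""

    panel_name: str
    peptide_ids: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.peptide_ids) == 0:
            raise ValueError("panel must contain at least one peptide")
        if len(set(self.peptide_ids)) != len(self.peptide_ids):
            raise ValueError(f"panel {self.panel_name!r} has duplicate peptide ids")

    def __len__(self) -> int:
        return len(self.peptide_ids)

    def __contains__(self, peptide_id: object) -> bool:
        return peptide_id in set(self.peptide_ids)


def default_panel(name: str) -> PanelDefinition:
    """Return a packaged default panel: ``"STK"`` (144 peptides) or ``"PTK"`` (196)."""
    sizes = {"STK": STK_PANEL_SIZE, "PTK": PTK_PANEL_SIZE}
    key = name.upper()
    if key not in sizes:
        raise KeyError(f"unknown panel {name!r}; available: {sorted(sizes)}")
    ids = tuple(f"{key}_{i:03d}" for i in range(1, sizes[key] + 1))
    return PanelDefinition(panel_name=key, peptide_ids=ids)


def make_panel(name: str, n_peptides: int) -> PanelDefinition:
    """Build an arbitrary-size synthetic panel (mainly for small test fixtures)."""
    if n_peptides < 1:
        raise ValueError("n_peptides must be >= 1")
    return PanelDefinition(name, tuple(f"{name}_{i:03d}" for i in range(1, n_peptides + 1)))
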