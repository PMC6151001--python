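"""A minimal multiple-sequence-alignment container."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .substitution import GAP, SubstModel

__all__ = ["Alignment"]


@dataclass(frozen=True)
class Alignment:
    """An MSA as equal-length gapped rows keyed by taxon labels."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows must have equal length")

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "Alignment":
        return cls(tuple(d.keys()), tuple(d.values()))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def reorder(self, taxa: list[str] | tuple[str, ...]) -> "Alignment":
        """Return the same alignment with rows in the given taxon order."""
        if set(taxa) != set(self.taxa):
            raise ValueError("taxon sets differ")
        return Alignment(tuple(taxa), tuple(self.row(t) for t in taxa))

    def restrict(self, taxa: list[str]) -> "Alignment":
        """Project onto a taxon subset, dropping columns left all-gap."""
        rows = [self.row(t) for t in taxa]
        keep = [j for j in range(self.n_cols) if any(r[j] != GAP for r in rows)]
        return Alignment(tuple(taxa), tuple("".join(r[j] for j in keep) for r in rows))

    def column(self, j: int) -> dict[str, str]:
        return {t: r[j] for t, r in zip(self.taxa, self.rows)}

    def has_all_gap_column(self) -> bool:
        return any(
            all(r[j] == GAP for r in self.rows) for j in range(self.n_cols)
        )

    def leaf_indicators(self, model: SubstModel) -> np.ndarray:
        """Per-leaf partial-likelihood tensor, shape (n_taxa, n_cols, |Σ|+1)."""
        out = np.zeros((self.n_taxa, self.n_cols, model.n_states + 1))
        for i, r in enumerate(self.rows):
            for j, ch in enumerate(r):
                out[i, j] = model.indicator(ch)
        return out
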