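"""FASTA reading/writing and run configuration."""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .msa import Alignment
from .substitution import GAP, SubstModel

__all__ = ["read_fasta", "write_alignment", "write_report"]


def read_fasta(
    path: str | Path,
    model: SubstModel | None = None,
    allow_gaps: bool = False,
) -> dict[str, str]:
    """Read a FASTA file into an ordered taxon → sequence map.

    Symbols are uppercased and validated against the model alphabet
    (plus its ambiguity codes) when a model is given.  Gaps ('-') are
    accepted only when ``allow_gaps`` is set — aligned inputs are for
    scoring, never for aligning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: dict[str, str] = {}
    for rec in records:
        if rec.id in out:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq):
            if ch == GAP:
                if not allow_gaps:
                    raise ValueError(
                        f"record {rec.id!r} position {pos + 1}: gaps are alignment "
                        "output, not aligner input"
                    )
                continue
            if model is not None:
                try:
                    model.indicator(ch)
                except Exception:
                    raise ValueError(
                        f"record {rec.id!r} position {pos + 1}: symbol {ch!r} "
                        f"is not valid under the {model.name} alphabet"
                    ) from None
        out[rec.id] = seq
    return out


def write_alignment(aln: Alignment, path: str | Path, fmt: str = "fasta") -> None:
    """Write an alignment as wrapped FASTA or a simple clustal-like block."""
    path = Path(path)
    if fmt == "fasta":
        records = [
            SeqRecord(Seq(row), id=taxon, description="")
            for taxon, row in zip(aln.taxa, aln.rows)
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    elif fmt == "clustal":
        width = max(len(t) for t in aln.taxa) + 2
        with open(path, "w") as fh:
            fh.write("CLUSTAL-like alignment\n\n")
            for start in range(0, max(aln.n_cols, 1), 60):
                for taxon, row in zip(aln.taxa, aln.rows):
                    fh.write(f"{taxon:<{width}}{row[start:start + 60]}\n")
                fh.write("\n")
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")


def write_report(path: str | Path, payload: dict) -> None:
    """Deterministic JSON sidecar with parameters, seed and diagnostics."""
    from . import __version__

    payload = {"pipalign_version": __version__, **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
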