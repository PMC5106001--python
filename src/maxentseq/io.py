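"""FASTA and profile file handling, plus CDS composition extraction."""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .genetic_code import (
    AminoAcidProfile,
    CodonTable,
    load_codon_table,
    profile_from_sequence,
    translate,
)
from .generators import GeneratedSequence

__all__ = [
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "profile_and_gc_from_cds",
    "read_profile",
    "write_profile",
]


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (header, uppercased sequence) records from a FASTA file.

    Wrapped and unwrapped records are both accepted; sequence data before
    the first header, or an empty record, is a parse error.
    """
    text = Path(path).read_text()
    for i, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaParseError("sequence data before first '>' header", i)
        break
    records = [
        (rec.description, str(rec.seq).upper())
        for rec in SeqIO.parse(_io.StringIO(text), "fasta")
    ]
    if not records:
        raise FastaParseError("no FASTA records found", 1)
    for header, seq in records:
        if not seq:
            raise FastaParseError(f"empty sequence for record {header!r}", 1)
    return records


def write_fasta(
    sequences: Sequence[GeneratedSequence] | Iterable[tuple[str, str]],
    path: str | Path,
    width: int = 60,
) -> None:
    """Write records to FASTA; generated sequences get key=value headers."""
    lines: list[str] = []
    for i, item in enumerate(sequences):
        if isinstance(item, GeneratedSequence):
            header, seq = item.fasta_header(i), item.full_nt
        else:
            header, seq = item
        lines.append(f">{header}")
        lines.extend(seq[j : j + width] for j in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")


def profile_and_gc_from_cds(
    nt_sequence: str, table: CodonTable | None = None
) -> tuple[AminoAcidProfile, float, int]:
    """Amino-acid profile, GC fraction and residue length of a CDS.

    The sequence must be in frame from position 1; a trailing stop codon is
    dropped and excluded from the GC fraction (GC is computed over the sense
    codons only, matching what the generators control).
    """
    if table is None:
        table = load_codon_table(1)
    aa = translate(nt_sequence, table)
    sense_nt = nt_sequence.upper()[: 3 * len(aa)]
    gc = (sense_nt.count("G") + sense_nt.count("C")) / len(sense_nt)
    return profile_from_sequence(aa), gc, len(aa)


def read_profile(path: str | Path) -> AminoAcidProfile:
    """Two-column text profile: residue, frequency (whitespace separated)."""
    freqs: dict[str, float] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise ValueError(f"line {i}: expected 'residue frequency', got {line!r}")
        freqs[parts[0].upper()] = float(parts[1])
    total = sum(freqs.values())
    if total <= 0:
        raise ValueError("profile file has no positive frequencies")
    return AminoAcidProfile({aa: v / total for aa, v in freqs.items()})


def write_profile(profile: AminoAcidProfile, path: str | Path) -> None:
    lines = [f"{aa}\t{f:.10f}" for aa, f in profile.frequencies.items()]
    Path(path).write_text("\n".join(lines) + "\n")
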