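"""Genetic-code structure: codon tables, G/C counts, and amino-acid profiles.

The maximum-entropy sampler only needs the *degeneracy structure* of the
genetic code — which codons encode which residue, and how many G/C
nucleotides each codon carries. Codon-to-residue assignments come from the
NCBI translation tables shipped with Biopython; everything layered on top
(synonymous families, per-codon G/C counts, composition extraction) lives
here.

Codons are DNA-alphabet trinucleotides (T, not U). The amino-acid alphabet
is strictly the 20 standard residues; ambiguity codes and the rare residues
U (selenocysteine) and O (pyrrolysine) are rejected rather than remapped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data import CodonTable as _ncbi

NUCLEOTIDES = "ACGT"
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(STANDARD_AMINO_ACIDS)


class InvalidCodonError(ValueError):
    """Raised for strings that are not length-3 words over {A,C,G,T}."""


class UnsupportedTableError(ValueError):
    """Raised for translation-table identifiers Biopython does not know."""


class PrematureStopError(ValueError):
    """Raised when a coding sequence contains an in-frame internal stop."""


class FrameError(ValueError):
    """Raised when a nucleotide sequence length is not a multiple of 3."""


class UnsupportedResidueError(ValueError):
    """Raised for residues outside the 20 standard amino acids."""


def gc_count(codon: str) -> int:
    """Number of G or C nucleotides in a codon (the observable E_C).

    Parameters
    ----------
    codon : str
        A trinucleotide over {A, C, G, T}; case-insensitive.

    Returns
    -------
    int
        Count in {0, 1, 2, 3}.
    """
    c = codon.upper()
    if len(c) != 3 or any(b not in NUCLEOTIDES for b in c):
        raise InvalidCodonError(f"not a valid ACGT codon: {codon!r}")
    return c.count("G") + c.count("C")


@dataclass(frozen=True)
class CodonTable:
    """A translation table with the derived structure the sampler needs.

    Attributes
    ----------
    table_id : int
        NCBI translation-table identifier (1 = standard code).
    codon_to_aa : Mapping[str, str]
        Sense codon -> one-letter amino acid.
    stop_codons : tuple[str, ...]
        Stop codons of the table.
    synonymous_families : Mapping[str, tuple[str, ...]]
        Amino acid -> its codons, sorted lexicographically. The family size
        is the degeneracy number m(a).
    gc_counts : Mapping[str, int]
        Codon -> number of G/C nucleotides, for all 64 codons.
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    stop_codons: tuple[str, ...]
    synonymous_families: Mapping[str, tuple[str, ...]] = field(init=False)
    gc_counts: Mapping[str, int] = field(init=False)

    def __post_init__(self) -> None:
        seen = set(self.codon_to_aa) | set(self.stop_codons)
        if len(seen) != 64 or len(self.codon_to_aa) + len(self.stop_codons) != 64:
            raise ValueError("codon table must partition all 64 codons into sense and stop sets")
        fams: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            if aa not in _AA_SET:
                raise UnsupportedResidueError(f"non-standard residue {aa!r} in table")
            fams.setdefault(aa, []).append(codon)
        object.__setattr__(
            self,
            "synonymous_families",
            {aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())},
        )
        all_codons = sorted(seen)
        object.__setattr__(self, "gc_counts", {c: gc_count(c) for c in all_codons})

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(self.synonymous_families)

    def degeneracy(self, aa: str) -> int:
        """Degeneracy number m(a): size of the synonymous family of ``aa``."""
        return len(self.synonymous_families[aa])

    def to_tsv(self) -> str:
        """Serialize as tab-separated (codon, amino_acid, is_stop) rows."""
        lines = ["codon\tamino_acid\tis_stop"]
        for codon in sorted(set(self.codon_to_aa) | set(self.stop_codons)):
            if codon in self.stop_codons:
                lines.append(f"{codon}\t*\t1")
            else:
                lines.append(f"{codon}\t{self.codon_to_aa[codon]}\t0")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, table_id: int = 0) -> "CodonTable":
        codon_to_aa: dict[str, str] = {}
        stops: list[str] = []
        rows = [ln for ln in text.strip().splitlines() if ln.strip()]
        for row in rows[1:]:
            codon, aa, is_stop = row.split("\t")
            if is_stop == "1":
                stops.append(codon)
            else:
                codon_to_aa[codon] = aa
        return cls(table_id=table_id, codon_to_aa=codon_to_aa, stop_codons=tuple(stops))


def load_codon_table(table_id: int = 1) -> CodonTable:
    """Load an NCBI translation table by identifier (1 = standard code)."""
    try:
        bio = _ncbi.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise UnsupportedTableError(
            f"unsupported NCBI translation table id: {table_id}"
        ) from exc
    return CodonTable(
        table_id=table_id,
        codon_to_aa=dict(bio.forward_table),
        stop_codons=tuple(sorted(bio.stop_codons)),
    )


def translate(nt_sequence: str, table: CodonTable | None = None) -> str:
    """Translate an in-frame coding sequence; a single trailing stop is dropped.

    Raises
    ------
    FrameError
        If the length is not a multiple of 3.
    PrematureStopError
        If a stop codon occurs before the final position.
    """
    if table is None:
        table = load_codon_table(1)
    nt = nt_sequence.upper()
    if len(nt) % 3 != 0:
        raise FrameError(f"sequence length {len(nt)} is not a multiple of 3")
    aas: list[str] = []
    n_codons = len(nt) // 3
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3]
        if any(b not in NUCLEOTIDES for b in codon):
            raise InvalidCodonError(f"non-ACGT codon {codon!r} at position {3 * i}")
        if codon in table.stop_codons:
            if i == n_codons - 1:
                break
            raise PrematureStopError(f"internal stop codon {codon} at codon index {i}")
        aas.append(table.codon_to_aa[codon])
    return "".join(aas)


@dataclass(frozen=True)
class AminoAcidProfile:
    """Normalized frequency vector f(a) over the 20 standard residues."""

    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        freqs = dict(self.frequencies)
        extra = set(freqs) - _AA_SET
        if extra:
            raise UnsupportedResidueError(
                f"unsupported residue(s) in profile: {sorted(extra)}"
            )
        for aa in STANDARD_AMINO_ACIDS:
            freqs.setdefault(aa, 0.0)
        if any(v < 0 for v in freqs.values()):
            raise ValueError("profile frequencies must be nonnegative")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile frequencies must sum to 1 (got {total!r})")
        object.__setattr__(
            self, "frequencies", {aa: freqs[aa] for aa in STANDARD_AMINO_ACIDS}
        )

    def __getitem__(self, aa: str) -> float:
        return self.frequencies[aa]

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(aa for aa, f in self.frequencies.items() if f > 0)

    @classmethod
    def uniform(cls) -> "AminoAcidProfile":
        return cls({aa: 1.0 / 20.0 for aa in STANDARD_AMINO_ACIDS})

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "AminoAcidProfile":
        total = float(sum(counts.values()))
        if total <= 0:
            raise ValueError("counts must be positive")
        return cls({aa: v / total for aa, v in counts.items()})


def profile_from_sequence(aa_sequence: str) -> AminoAcidProfile:
    """Empirical residue frequencies of a protein sequence."""
    if not aa_sequence:
        raise ValueError("amino-acid sequence must be nonempty")
    seq = aa_sequence.upper()
    bad = set(seq) - _AA_SET
    if bad:
        raise UnsupportedResidueError(
            f"unsupported residue(s) {sorted(bad)} in sequence"
        )
    return AminoAcidProfile.from_counts(Counter(seq))
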