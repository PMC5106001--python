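"""Random coding-sequence generators.

Four sampling schemes over synonymous codons, all preserving the amino-acid
sequence exactly:

* ``generate_maxent`` — the maximum-entropy policy at the solved beta; the
  observed GC of replicates is Gaussian around the target (the method of
  interest).
* ``generate_naive`` — uniform choice within each synonymous family; the GC
  content lands wherever the amino-acid composition dictates (~0.47 for
  uniform usage).
* ``generate_rejection`` — naive draws filtered to a GC window; slow, and
  the accepted GC distribution piles up against the window bound nearest
  the naive mean.
* ``generate_multinomial`` — codon weights proportional to the product of
  target per-position nucleotide frequencies; fails to achieve the target
  composition (kept as a documented negative control).

``generate_gc_range`` produces sequences whose GC is approximately uniform
over a window by drawing a fresh point target per sequence from a slightly
expanded window and rejecting out-of-window results.

Sequences never contain in-frame stop codons. No start codon is forced; a
stop codon is only appended on request, and an appended stop is excluded
from GC accounting (the GC constraint is defined over the sense codons).
Each replicate k of a call seeded with s uses the independent RNG stream
seeded by (s, k), so outputs are reproducible byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genetic_code import (
    AminoAcidProfile,
    CodonTable,
    load_codon_table,
    profile_from_sequence,
)
from .maxent import (
    BetaLookup,
    CodonPolicy,
    GCTarget,
    InfeasibleTargetError,
    codon_policy,
    feasible_gc_range,
    solve_beta,
)

__all__ = [
    "GeneratedSequence",
    "NucleotideComposition",
    "RejectionBudgetError",
    "RangeBudgetError",
    "DegenerateCompositionError",
    "random_aa_sequence",
    "generate_maxent",
    "generate_naive",
    "generate_rejection",
    "multinomial_policy",
    "generate_multinomial",
    "generate_gc_range",
]


class RejectionBudgetError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""

    def __init__(self, attempts: int):
        self.attempts = attempts
        super().__init__(f"no sequence accepted after {attempts} attempts")


class RangeBudgetError(RuntimeError):
    """GC-range mode fell below its acceptance-rate floor."""


class DegenerateCompositionError(ValueError):
    """A synonymous family has zero total weight under the composition."""


@dataclass(frozen=True)
class NucleotideComposition:
    """Target (or observed) mononucleotide fractions."""

    g: float
    c: float
    a: float
    t: float

    def __post_init__(self) -> None:
        vals = (self.g, self.c, self.a, self.t)
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("nucleotide fractions must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"nucleotide fractions must sum to 1 (got {sum(vals)!r})")

    @property
    def gc(self) -> float:
        return self.g + self.c

    def fraction(self, base: str) -> float:
        return {"G": self.g, "C": self.c, "A": self.a, "T": self.t}[base.upper()]

    @classmethod
    def from_gc(cls, gc: float) -> "NucleotideComposition":
        """Even split: G = C = gc/2, A = T = (1-gc)/2."""
        return cls(g=gc / 2, c=gc / 2, a=(1 - gc) / 2, t=(1 - gc) / 2)


@dataclass(frozen=True)
class GeneratedSequence:
    """A generated coding sequence with its provenance.

    ``nt`` covers the sense codons only (3 * len(aa) nucleotides); an
    appended stop codon, if any, is stored separately and excluded from
    ``observed_gc``.
    """

    nt: str
    aa: str
    method: str
    seed: int
    replicate: int = 0
    beta: float | None = None
    target_gc: float | None = None
    stop_codon: str | None = None
    attempts: int = 1

    @property
    def observed_gc(self) -> float:
        return (self.nt.count("G") + self.nt.count("C")) / len(self.nt)

    @property
    def observed_nt_freqs(self) -> NucleotideComposition:
        n = len(self.nt)
        return NucleotideComposition(
            g=self.nt.count("G") / n,
            c=self.nt.count("C") / n,
            a=self.nt.count("A") / n,
            t=self.nt.count("T") / n,
        )

    @property
    def full_nt(self) -> str:
        """Sense codons plus the appended stop codon, if any."""
        return self.nt + (self.stop_codon or "")

    def fasta_header(self, index: int = 0) -> str:
        parts = [f"seq{index}", f"method={self.method}"]
        if self.target_gc is not None:
            parts.append(f"target_gc={self.target_gc:.6f}")
        parts.append(f"observed_gc={self.observed_gc:.6f}")
        if self.beta is not None:
            parts.append(f"beta={self.beta:.6g}")
        parts.append(f"seed={self.seed}")
        return " ".join(parts)


def _rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def random_aa_sequence(
    profile: AminoAcidProfile, length_aa: int, rng_seed: int | np.random.Generator = 0
) -> str:
    """An i.i.d. residue sequence drawn from the profile ("bag of marbles")."""
    if length_aa < 1:
        raise ValueError("length_aa must be >= 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else _rng(rng_seed, 0)
    aas = np.array(list(profile.frequencies), dtype="U1")
    probs = np.fromiter(profile.frequencies.values(), dtype=float)
    idx = rng.choice(len(aas), size=length_aa, p=probs)
    return "".join(aas[idx])


class _PolicySampler:
    """Vectorized per-residue codon sampler for a fixed policy.

    Precomputes, per amino acid, the codon list and cumulative probabilities
    so a whole sequence is sampled with one uniform draw per residue and a
    vectorized cumulative-probability inversion.
    """

    def __init__(self, policy: CodonPolicy, table: CodonTable):
        self.aa_index = {aa: i for i, aa in enumerate(table.amino_acids)}
        n_aa = len(self.aa_index)
        max_fam = max(len(f) for f in table.synonymous_families.values())
        self._cum = np.ones((n_aa, max_fam))
        self._codons = np.empty((n_aa, max_fam), dtype="U3")
        self._gc = np.zeros((n_aa, max_fam), dtype=np.int64)
        for aa, i in self.aa_index.items():
            fam = table.synonymous_families[aa]
            p = np.array([policy.probability(aa, c) for c in fam])
            self._cum[i, : len(fam)] = np.cumsum(p)
            self._cum[i, len(fam) - 1] = 1.0  # guard against rounding
            self._codons[i, : len(fam)] = fam
            self._codons[i, len(fam):] = fam[-1]
            self._gc[i, : len(fam)] = [table.gc_counts[c] for c in fam]

    def sample(self, aa_sequence: str, rng: np.random.Generator) -> str:
        ai = np.array([self.aa_index[a] for a in aa_sequence])
        u = rng.random(len(ai))
        choice = (u[:, None] > self._cum[ai]).sum(axis=1)
        return "".join(self._codons[ai, choice])


def _resolve_inputs(
    aa_or_profile: str | AminoAcidProfile,
    length_aa: int | None,
) -> tuple[AminoAcidProfile, str | None, int]:
    """Normalize the (sequence | profile, length) calling convention."""
    if isinstance(aa_or_profile, AminoAcidProfile):
        if length_aa is None:
            raise ValueError("length_aa is required when a profile is given")
        return aa_or_profile, None, int(length_aa)
    aa = str(aa_or_profile).upper()
    return profile_from_sequence(aa), aa, len(aa)


def _generate_from_policy(
    policy: CodonPolicy,
    aa_or_profile: str | AminoAcidProfile,
    length_aa: int | None,
    table: CodonTable,
    rng_seed: int,
    n_sequences: int,
    method: str,
    beta: float | None = None,
    target_gc: float | None = None,
    append_stop: bool = False,
) -> list[GeneratedSequence]:
    profile, fixed_aa, n = _resolve_inputs(aa_or_profile, length_aa)
    sampler = _PolicySampler(policy, table)
    out: list[GeneratedSequence] = []
    for k in range(n_sequences):
        rng = _rng(rng_seed, k)
        aa = fixed_aa if fixed_aa is not None else random_aa_sequence(profile, n, rng)
        nt = sampler.sample(aa, rng)
        stop = (
            str(rng.choice(np.array(table.stop_codons))) if append_stop else None
        )
        out.append(
            GeneratedSequence(
                nt=nt,
                aa=aa,
                method=method,
                seed=rng_seed,
                replicate=k,
                beta=beta,
                target_gc=target_gc,
                stop_codon=stop,
            )
        )
    return out


def generate_maxent(
    aa_or_profile: str | AminoAcidProfile,
    length_aa: int | None = None,
    target: GCTarget | float = 0.5,
    table: CodonTable | None = None,
    rng_seed: int = 0,
    n_sequences: int = 1,
    append_stop: bool = False,
    tolerance: float = 1e-10,
) -> list[GeneratedSequence]:
    """Sequences from the maximum-entropy policy at the solved beta.

    When an explicit amino-acid sequence is supplied, beta is solved against
    that sequence's empirical profile and codons are assigned to that exact
    sequence. Raises :class:`InfeasibleTargetError` for unattainable targets.
    """
    if table is None:
        table = load_codon_table(1)
    if isinstance(target, GCTarget):
        if target.mode != "point":
            raise ValueError("generate_maxent takes a point target; see generate_gc_range")
        target_value = float(target.value)
    else:
        target_value = float(target)
    profile, _, _ = _resolve_inputs(aa_or_profile, length_aa)
    sol = solve_beta(profile, target_value, table, tolerance=tolerance)
    return _generate_from_policy(
        sol.policy,
        aa_or_profile,
        length_aa,
        table,
        rng_seed,
        n_sequences,
        method="maxent",
        beta=sol.beta,
        target_gc=target_value,
        append_stop=append_stop,
    )


def generate_naive(
    aa_or_profile: str | AminoAcidProfile,
    length_aa: int | None = None,
    table: CodonTable | None = None,
    rng_seed: int = 0,
    n_sequences: int = 1,
    append_stop: bool = False,
) -> list[GeneratedSequence]:
    """Uniform synonymous-codon choice (the beta = 0 policy)."""
    if table is None:
        table = load_codon_table(1)
    return _generate_from_policy(
        codon_policy(table, 0.0),
        aa_or_profile,
        length_aa,
        table,
        rng_seed,
        n_sequences,
        method="naive",
        beta=0.0,
        append_stop=append_stop,
    )


def generate_rejection(
    aa_or_profile: str | AminoAcidProfile,
    length_aa: int | None = None,
    gc_lo: float = 0.0,
    gc_hi: float = 1.0,
    table: CodonTable | None = None,
    rng_seed: int = 0,
    max_attempts: int = 10_000,
    append_stop: bool = False,
) -> GeneratedSequence:
    """First naive draw whose GC falls in [gc_lo, gc_hi].

    Attempt count is recorded on the result. When the window excludes the
    naive mean, accepted GC values pile up against the nearer bound — the
    bias this baseline is known for.
    """
    if not gc_lo < gc_hi:
        raise ValueError("require gc_lo < gc_hi")
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    if table is None:
        table = load_codon_table(1)
    policy = codon_policy(table, 0.0)
    for attempt in range(max_attempts):
        (seq,) = _generate_from_policy(
            policy,
            aa_or_profile,
            length_aa,
            table,
            rng_seed + attempt,
            1,
            method="rejection",
            beta=0.0,
            append_stop=append_stop,
        )
        if gc_lo <= seq.observed_gc <= gc_hi:
            return GeneratedSequence(
                nt=seq.nt,
                aa=seq.aa,
                method="rejection",
                seed=rng_seed,
                replicate=0,
                beta=0.0,
                stop_codon=seq.stop_codon,
                attempts=attempt + 1,
            )
    raise RejectionBudgetError(max_attempts)


def multinomial_policy(
    target: NucleotideComposition, table: CodonTable | None = None
) -> CodonPolicy:
    """Codon weights proportional to the product of per-position nucleotide
    frequencies, normalized within each synonymous family."""
    if table is None:
        table = load_codon_table(1)
    probs: dict[str, dict[str, float]] = {}
    for aa, codons in table.synonymous_families.items():
        w = np.array(
            [math.prod(target.fraction(b) for b in codon) for codon in codons]
        )
        total = w.sum()
        if total <= 0.0:
            raise DegenerateCompositionError(
                f"every codon of {aa} has zero probability under the composition"
            )
        probs[aa] = {c: float(p) for c, p in zip(codons, w / total)}
    return CodonPolicy(probs)


def generate_multinomial(
    aa_or_profile: str | AminoAcidProfile,
    length_aa: int | None = None,
    target: NucleotideComposition | None = None,
    table: CodonTable | None = None,
    rng_seed: int = 0,
    n_sequences: int = 1,
    append_stop: bool = False,
) -> list[GeneratedSequence]:
    """Sequences from the multinomial baseline policy.

    The achieved composition does not generally match ``target``; this
    generator exists to demonstrate that failure.
    """
    if table is None:
        table = load_codon_table(1)
    if target is None:
        raise ValueError("a target NucleotideComposition is required")
    return _generate_from_policy(
        multinomial_policy(target, table),
        aa_or_profile,
        length_aa,
        table,
        rng_seed,
        n_sequences,
        method="multinomial",
        target_gc=target.gc,
        append_stop=append_stop,
    )


def default_expansion(gc_lo: float, gc_hi: float, length_aa: int) -> float:
    """Gaussian-fluctuation heuristic for the range-mode window expansion.

    3 standard deviations of a binomial GC fraction at the window midpoint:
    3 * sqrt(g(1-g) / (3N)).
    """
    g = 0.5 * (gc_lo + gc_hi)
    return 3.0 * math.sqrt(g * (1.0 - g) / (3.0 * length_aa))


def generate_gc_range(
    aa_or_profile: str | AminoAcidProfile,
    length_aa: int | None = None,
    target: GCTarget | None = None,
    n_sequences: int = 1,
    table: CodonTable | None = None,
    rng_seed: int = 0,
    expansion: float | None = None,
    append_stop: bool = False,
    max_attempts_factor: int = 50,
) -> list[GeneratedSequence]:
    """Sequences whose observed GC is ~uniform over a window [lo, hi].

    Per sequence, a point target is drawn uniformly from the window expanded
    by ``expansion`` on each side (clipped to the feasible range), beta comes
    from a precomputed monotone GC -> beta lookup, and the draw is kept only
    if its observed GC lands inside the unexpanded window. The expansion
    defaults to :func:`default_expansion`, which covers the Gaussian spread
    of a single draw, so the accepted values fill the window edges uniformly
    instead of decaying there.
    """
    if table is None:
        table = load_codon_table(1)
    if target is None or target.mode != "range":
        raise ValueError("generate_gc_range requires a range-mode GCTarget")
    profile, fixed_aa, n = _resolve_inputs(aa_or_profile, length_aa)
    lo, hi = float(target.lo), float(target.hi)
    flo, fhi = feasible_gc_range(profile, table)
    if hi <= flo or lo >= fhi:
        raise InfeasibleTargetError((lo + hi) / 2, flo, fhi)
    delta = default_expansion(lo, hi, n) if expansion is None else float(expansion)
    lookup = BetaLookup(profile, table)
    draw_lo = max(lo - delta, lookup.gc_min)
    draw_hi = min(hi + delta, lookup.gc_max)
    out: list[GeneratedSequence] = []
    max_attempts = max_attempts_factor * n_sequences
    attempt = 0
    k = 0
    while len(out) < n_sequences:
        if attempt >= max_attempts:
            raise RangeBudgetError(
                f"accepted {len(out)}/{n_sequences} sequences in {attempt} attempts"
            )
        rng = _rng(rng_seed, attempt)
        point = rng.uniform(draw_lo, draw_hi)
        beta = lookup.beta_for(point)
        policy = codon_policy(table, beta)
        sampler = _PolicySampler(policy, table)
        aa = fixed_aa if fixed_aa is not None else random_aa_sequence(profile, n, rng)
        nt = sampler.sample(aa, rng)
        attempt += 1
        gc = (nt.count("G") + nt.count("C")) / len(nt)
        if lo <= gc <= hi:
            stop = (
                str(rng.choice(np.array(table.stop_codons))) if append_stop else None
            )
            out.append(
                GeneratedSequence(
                    nt=nt,
                    aa=aa,
                    method="maxent-range",
                    seed=rng_seed,
                    replicate=k,
                    beta=float(beta),
                    target_gc=float(point),
                    stop_codon=stop,
                    attempts=attempt,
                )
            )
            k += 1
    return out
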