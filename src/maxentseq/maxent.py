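"""Maximum-entropy codon-usage policies under a GC-content constraint.

Among all per-residue synonymous-codon distributions whose expected number
of G/C nucleotides equals a target, the one with maximal entropy is a
Boltzmann family with a single Lagrange parameter beta:

    P(C | a) = exp(-beta * E_C) / Z(a, beta)

where E_C is the G/C count of codon C and Z(a, beta) normalizes within the
synonymous family of amino acid a. The induced expected GC fraction

    g(beta) = (1/3) * sum_a f(a) * <E_C>_{P(.|a, beta)}

is strictly decreasing in beta (whenever some occupied family has codons of
unequal E_C), so the beta matching any attainable target is found by
bracketing and a guaranteed root method. Large positive beta favours AT-rich
codons; large negative beta favours GC-rich codons; beta = 0 is uniform
synonymous choice.

The attainable GC contents form a closed interval determined purely by the
genetic code and the amino-acid profile: the frequency-weighted per-family
minimum and maximum E_C, divided by 3. Targets outside it are infeasible —
no codon choice can realize them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .genetic_code import AminoAcidProfile, CodonTable, load_codon_table

__all__ = [
    "GCTarget",
    "CodonPolicy",
    "MaxEntSolution",
    "InfeasibleTargetError",
    "codon_policy",
    "expected_gc",
    "feasible_gc_range",
    "solve_beta",
    "BetaLookup",
]


class InfeasibleTargetError(ValueError):
    """Target GC content outside the profile's attainable interval."""

    def __init__(self, target: float, lo: float, hi: float):
        self.target = target
        self.lo = lo
        self.hi = hi
        super().__init__(
            f"target GC {target:.6f} outside the feasible range "
            f"[{lo:.6f}, {hi:.6f}] for this amino-acid profile"
        )


@dataclass(frozen=True)
class GCTarget:
    """A GC-content constraint: a point target or an allowable range."""

    mode: str  # "point" | "range"
    value: float | None = None
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "point":
            if self.value is None or not (0.0 < self.value < 1.0):
                raise ValueError("point target requires 0 < value < 1")
        elif self.mode == "range":
            if self.lo is None or self.hi is None or not (0.0 < self.lo <= self.hi < 1.0):
                raise ValueError("range target requires 0 < lo <= hi < 1")
        else:
            raise ValueError(f"unknown GC target mode {self.mode!r}")

    @classmethod
    def point(cls, value: float) -> "GCTarget":
        return cls(mode="point", value=value)

    @classmethod
    def range(cls, lo: float, hi: float) -> "GCTarget":
        return cls(mode="range", lo=lo, hi=hi)


@dataclass(frozen=True)
class CodonPolicy:
    """Per amino acid, a probability distribution over its synonymous codons."""

    probabilities: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        probs = {
            aa: dict(dist) for aa, dist in self.probabilities.items()
        }
        for aa, dist in probs.items():
            vals = list(dist.values())
            if any(p < 0 for p in vals):
                raise ValueError(f"negative probability in family {aa}")
            if abs(sum(vals) - 1.0) > 1e-12:
                raise ValueError(
                    f"family {aa} probabilities sum to {sum(vals)!r}, expected 1"
                )
        object.__setattr__(self, "probabilities", probs)

    def __getitem__(self, aa: str) -> Mapping[str, float]:
        return self.probabilities[aa]

    def probability(self, aa: str, codon: str) -> float:
        return self.probabilities[aa].get(codon, 0.0)

    def to_rows(self) -> list[tuple[str, str, float]]:
        """Flatten to (amino_acid, codon, probability) rows, sorted."""
        rows = []
        for aa in sorted(self.probabilities):
            for codon in sorted(self.probabilities[aa]):
                rows.append((aa, codon, self.probabilities[aa][codon]))
        return rows


def _family_weights(energies: np.ndarray, beta: float) -> np.ndarray:
    """Boltzmann weights exp(-beta*E) within one family, overflow-safe.

    Shifting by the extremal energy keeps every exponent <= 0, so the
    weights are exact up to underflow even for |beta| ~ 1e6.
    """
    shift = energies.min() if beta >= 0 else energies.max()
    return np.exp(-beta * (energies - shift))


def codon_policy(table: CodonTable, beta: float) -> CodonPolicy:
    """The maximum-entropy synonymous-codon distribution at a given beta.

    Within each synonymous family, P(C) = exp(-beta*E_C) / Z(a, beta).
    Infinite beta is accepted and yields the zero-temperature limit: all
    mass split uniformly over the family's minimal-E_C codons (+inf) or
    maximal-E_C codons (-inf).
    """
    probs: dict[str, dict[str, float]] = {}
    for aa, codons in table.synonymous_families.items():
        energies = np.array([table.gc_counts[c] for c in codons], dtype=float)
        if math.isinf(beta):
            extreme = energies.min() if beta > 0 else energies.max()
            mask = energies == extreme
            w = mask / mask.sum()
        else:
            w = _family_weights(energies, beta)
            w = w / w.sum()
        probs[aa] = {c: float(p) for c, p in zip(codons, w)}
    return CodonPolicy(probs)


def expected_gc(
    profile: AminoAcidProfile, beta: float, table: CodonTable | None = None
) -> float:
    """Expected GC fraction of sequences drawn under the policy at ``beta``.

    Length-independent: E[n_gc] / (3N) = (1/3) sum_a f(a) <E_C>_{a,beta}.
    """
    if table is None:
        table = load_codon_table(1)
    total = 0.0
    for aa, f in profile.frequencies.items():
        if f == 0.0:
            continue
        codons = table.synonymous_families[aa]
        energies = np.array([table.gc_counts[c] for c in codons], dtype=float)
        if math.isinf(beta):
            mean_e = energies.min() if beta > 0 else energies.max()
        else:
            w = _family_weights(energies, beta)
            mean_e = float((energies * w).sum() / w.sum())
        total += f * mean_e
    return total / 3.0


def feasible_gc_range(
    profile: AminoAcidProfile, table: CodonTable | None = None
) -> tuple[float, float]:
    """Attainable GC interval [lo, hi] for a profile.

    lo is the beta -> +inf limit (frequency-weighted minimum family E_C / 3),
    hi the beta -> -inf limit (maximum family E_C / 3). Any target strictly
    inside is reached by a finite beta; the endpoints only by the degenerate
    limit policies.
    """
    if table is None:
        table = load_codon_table(1)
    lo = hi = 0.0
    for aa, f in profile.frequencies.items():
        if f == 0.0:
            continue
        es = [table.gc_counts[c] for c in table.synonymous_families[aa]]
        lo += f * min(es)
        hi += f * max(es)
    return lo / 3.0, hi / 3.0


@dataclass(frozen=True)
class MaxEntSolution:
    """A solved GC constraint: beta, the induced policy, and diagnostics."""

    beta: float
    policy: CodonPolicy
    expected_gc: float
    profile: AminoAcidProfile
    target_gc: float
    residual: float
    feasible_range: tuple[float, float]
    boundary: bool = False

    def to_report(self) -> str:
        """Plain-text report: beta, targets, and the full codon table."""
        lines = [
            f"beta\t{self.beta:.12g}",
            f"target_gc\t{self.target_gc:.10f}",
            f"expected_gc\t{self.expected_gc:.10f}",
            f"residual\t{self.residual:.3e}",
            f"feasible_lo\t{self.feasible_range[0]:.10f}",
            f"feasible_hi\t{self.feasible_range[1]:.10f}",
            f"boundary\t{int(self.boundary)}",
            "amino_acid\tcodon\tprobability",
        ]
        for aa, codon, p in self.policy.to_rows():
            lines.append(f"{aa}\t{codon}\t{p:.10f}")
        return "\n".join(lines) + "\n"


# Beyond |beta| ~ 60 every family is numerically at its zero-temperature
# limit (exp(-60) ~ 9e-27), so this bracket bound is effectively infinite.
_BRACKET_MAX = 512.0


def solve_beta(
    profile: AminoAcidProfile,
    target_gc: float,
    table: CodonTable | None = None,
    tolerance: float = 1e-10,
    max_iter: int = 200,
) -> MaxEntSolution:
    """Solve for the beta whose expected GC fraction equals ``target_gc``.

    Brackets the root by doubling outward from beta = 0 (expected GC is
    strictly decreasing in beta) and polishes with Brent's method; the
    returned solution satisfies |expected_gc - target| <= tolerance. A
    target exactly at a feasibility endpoint returns the degenerate limit
    policy with ``boundary=True`` and infinite beta.
    """
    if table is None:
        table = load_codon_table(1)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    lo, hi = feasible_gc_range(profile, table)

    def _solution(beta: float, boundary: bool = False) -> MaxEntSolution:
        att = expected_gc(profile, beta, table)
        return MaxEntSolution(
            beta=beta,
            policy=codon_policy(table, beta),
            expected_gc=att,
            profile=profile,
            target_gc=target_gc,
            residual=abs(att - target_gc),
            feasible_range=(lo, hi),
            boundary=boundary,
        )

    if target_gc < lo - tolerance or target_gc > hi + tolerance:
        raise InfeasibleTargetError(target_gc, lo, hi)
    if abs(target_gc - lo) <= tolerance and lo < hi:
        # degenerate families only; check whether a finite beta suffices
        if target_gc <= lo:
            return _solution(math.inf, boundary=True)
    if abs(target_gc - hi) <= tolerance and target_gc >= hi:
        return _solution(-math.inf, boundary=True)
    if lo == hi:
        return _solution(math.inf, boundary=True)

    def f(beta: float) -> float:
        return expected_gc(profile, beta, table) - target_gc

    f0 = f(0.0)
    if abs(f0) <= tolerance:
        return _solution(0.0)
    # f is decreasing: f > 0 means the target lies below g(0), so move right.
    step = 1.0
    if f0 > 0:
        a, b = 0.0, step
        while f(b) > 0:
            a, b = b, b * 2.0
            if b > _BRACKET_MAX:
                return _solution(math.inf, boundary=True)
    else:
        a, b = -step, 0.0
        while f(a) < 0:
            a, b = a * 2.0, a
            if a < -_BRACKET_MAX:
                return _solution(-math.inf, boundary=True)
    beta = brentq(f, a, b, xtol=1e-14, rtol=8.9e-16, maxiter=max_iter)
    sol = _solution(float(beta))
    if sol.residual > tolerance:
        raise RuntimeError(
            f"root polish failed: residual {sol.residual:.3e} > tolerance {tolerance:.3e}"
        )
    return sol


class BetaLookup:
    """Monotone interpolation of the beta <-> GC relation for one profile.

    Solving beta afresh for every sequence in range mode is wasteful; the
    relation g(beta) is smooth and strictly monotone, so ~200 solved points
    and a PCHIP (shape-preserving) interpolant reproduce beta(g) to high
    accuracy across the interior of the feasible range.
    """

    def __init__(
        self,
        profile: AminoAcidProfile,
        table: CodonTable | None = None,
        n_points: int = 200,
        margin: float = 1e-4,
    ):
        if table is None:
            table = load_codon_table(1)
        self.profile = profile
        self.table = table
        self.lo, self.hi = feasible_gc_range(profile, table)
        span = self.hi - self.lo
        if span <= 0:
            raise ValueError("degenerate profile: feasible range is a single point")
        # relative margin keeps targets strictly interior
        eps = margin * span
        gcs = np.linspace(self.lo + eps, self.hi - eps, n_points)
        betas = np.array(
            [solve_beta(profile, g, table).beta for g in gcs]
        )
        # g decreasing in beta -> reverse for an increasing interpolant
        self._interp = PchipInterpolator(gcs, betas)
        self.gc_min = float(gcs[0])
        self.gc_max = float(gcs[-1])

    def beta_for(self, gc: float) -> float:
        """Interpolated beta for a GC target inside the tabulated interval."""
        g = float(np.clip(gc, self.gc_min, self.gc_max))
        return float(self._interp(g))
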