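# Methods

## Model

Sequences are generated codon by codon, conditional on an amino-acid
sequence that is either supplied directly or drawn i.i.d. from a frequency
profile f(a) over the 20 standard residues. The only nucleotide-level
constraint is the expected number of G/C nucleotides. Among all
per-residue synonymous-codon distributions with a given expected G/C
count, the entropy-maximizing one is the exponential family

    P(C | a) = exp(-beta * E_C) / Z(a, beta)

with E_C the G/C count of codon C and Z(a, beta) the within-family
normalizer. Because codon choices are independent given the protein, the
expected GC fraction is the frequency-weighted average of the per-family
Boltzmann means, divided by 3:

    g(beta) = (1/3) * sum_a f(a) * <E_C>_{a,beta}

The normalizer is applied *within each synonymous family*: this is the
only reading under which the expectation formula is dimensionally
consistent and exactly the expectation of the codon policy, and it
reproduces the analytic anchors (uniform-usage bounds 30%/63.3%, naive
mean 0.4694) that the package's tests check.

Assumptions worth stating: codon choices are independent across positions
(no di-nucleotide or codon-pair structure), the constraint is on the
*expected* GC (individual sequences fluctuate binomially, sd ≈
sqrt(g(1-g)/(3N))), and stop codons never enter the constraint — GC is
defined over sense codons only. Multi-constraint variants (individual
nucleotide or di-nucleotide frequencies, which require solving several
coupled Lagrange parameters) are out of scope.

## Solving beta

g(beta) is strictly decreasing whenever some occupied family has codons of
unequal E_C, and its limits are the frequency-weighted per-family minimum
(beta -> +inf) and maximum (beta -> -inf) E_C over 3. These limits are the
*feasible range*; targets outside it raise an error that reports the
range, and targets exactly at an endpoint return the degenerate
zero-temperature policy (mass split uniformly over the family's extremal
codons — the maximum-entropy choice among the degenerate optima) with a
boundary flag instead of a finite beta.

For interior targets the root of g(beta) - target is bracketed by doubling
outward from beta = 0 and polished with Brent's method (scipy), then
checked against the tolerance, which is expressed on the GC-fraction
residual (default 1e-10). Family weights are computed as
exp(-beta * (E - E_extreme)) so every exponent is <= 0; this keeps the
evaluation exact up to underflow for |beta| as large as 1e6, which the
tests use to confirm the limits. In practice every representable interior
target brackets within |beta| < 60 because the families differ by integer
E_C steps.

## Generators

All four samplers share one vectorized path: per amino acid, cumulative
codon probabilities are precomputed and each residue's codon is found by
inverting a single uniform draw. Replicate k of a call seeded with s uses
the numpy stream seeded by SeedSequence([s, k]), so outputs are
byte-reproducible and replicates are independent.

* **maxent** — policy at the solved beta. When an explicit protein is
  given, beta is solved against that sequence's own empirical profile and
  codons are assigned to that exact sequence.
* **naive** — the beta = 0 policy (uniform within families); included as
  the no-control baseline.
* **rejection** — naive draws filtered to a GC window, with an attempt
  budget; kept because its accepted-GC distribution is demonstrably
  truncated-Gaussian, piling up against the window bound nearest the
  naive mean.
* **multinomial** — codon weights proportional to the product of target
  per-position nucleotide frequencies, renormalized within families. This
  baseline does not achieve its target composition (renormalization
  within unequal-size families shifts the realized frequencies); the
  evaluation harness quantifies the miss.

No start codon is forced and no stop codon is appended by default; an
optional flag appends one stop codon drawn uniformly from the table's stop
set, excluded from GC accounting. The genetic code defaults to NCBI
translation table 1; other tables are accepted by identifier, with the
degeneracy structure rebuilt from Biopython's table data.

## GC-range mode

To produce an ensemble whose GC is uniform over a window [lo, hi], each
sequence gets its own point target drawn uniformly from the window
expanded by delta on each side (clipped to the feasible range); the
sequence is kept only if its observed GC lands inside the unexpanded
window. The default delta = 3*sqrt(g(1-g)/(3N)) at the window midpoint
covers the Gaussian spread of a single draw, so the edge regions are
filled rather than left with decaying tails; delta = 0 reproduces the
tail-decay shape, and both behaviours are asserted in the tests. How the
per-sequence targets are chosen is a design decision of this package (the
uniform draw is the simplest mechanism that yields the documented uniform
outcome).

Solving beta afresh per sequence would dominate the cost, so a lookup of
~200 solved (GC, beta) pairs spanning the feasible interior is built once
per profile and interpolated with a shape-preserving PCHIP spline;
interpolation error is ~1e-6 in GC, far below the per-sequence sampling
noise. Acceptance is bounded by a budget of 50 attempts per requested
sequence; falling below that rate raises rather than loops forever.

## Numerical and design choices

* Tolerances: policy normalization is exact to 1e-12 per family; profile
  normalization to 1e-9; solver residual 1e-10 on the GC fraction.
* Targets are real-valued expectations; no rounding of the G/C count to an
  integer is applied before solving.
* Amino-acid alphabet is strictly the 20 standard residues; ambiguity
  codes and U/O are rejected, as are degenerate nucleotide codes in CDS
  input — GC content would be ill-defined otherwise.
* CDS inputs are assumed in frame from position 1 (no ORF scanning); a
  single trailing stop is dropped and excluded from the extracted GC.
* Ties at the zero-temperature limits split uniformly; beta is unbounded
  in sign and unregularized.

## What the synthetic experiments do and do not show

The experiment harnesses draw proteins i.i.d. from a profile — by design
they emulate composition constraints only, not the positional
autocorrelation, codon bias, or di-nucleotide structure of real genes.
Passing tests therefore certify that the sampler hits its composition
constraints unbiasedly, not that its output is indistinguishable from
genomic sequence in any richer statistic.

Default experiment scale matches the benchmark setting of 500 replicates
of 2500 residues; the test suite uses that scale where a claim is about
it (mean-GC accuracy, the multinomial negative result, range-mode
uniformity at n = 5,000) and a reduced scale (100 replicates of 500
residues, exposed as `FAST_SCALE`) for structural checks. At full scale
the Monte-Carlo standard error of a mean GC is about 2.6e-4, which is the
resolution at which "mean equals target" is asserted (4 standard errors).

Known limitations: a target GC of exactly 0.30 under uniform usage is the
feasibility boundary, generated by the degenerate policy rather than a
finite beta (the attained mean is exact but the per-sequence variance
collapses to the amino-acid sampling component); single-amino-acid
profiles with one codon (M, W) have a point feasible range and cannot be
range-sampled; and the multinomial baseline is intentionally faithful to
its flawed definition — it should not be used to hit a composition.
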