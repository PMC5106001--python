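import numpy as np
import pytest

from maxentseq import (
    AminoAcidProfile,
    GCTarget,
    InfeasibleTargetError,
    NucleotideComposition,
    generate_gc_range,
    generate_maxent,
    generate_multinomial,
    generate_naive,
    generate_rejection,
    multinomial_policy,
    random_aa_sequence,
    translate,
)
from maxentseq.generators import (
    DegenerateCompositionError,
    RejectionBudgetError,
    default_expansion,
)

from conftest import enumerate_gc_distribution


class TestRandomAaSequence:
    def test_degenerate_profile(self):
        assert random_aa_sequence(AminoAcidProfile({"A": 1.0}), 5, 0) == "AAAAA"

    def test_seed_determinism(self, uniform_profile):
        a = random_aa_sequence(uniform_profile, 200, rng_seed=11)
        b = random_aa_sequence(uniform_profile, 200, rng_seed=11)
        assert a == b
        assert a != random_aa_sequence(uniform_profile, 200, rng_seed=12)

    def test_empirical_frequencies_match_profile(self, uniform_profile):
        # pooled draws: each residue frequency ~ 0.05 within 4 SE
        n = 2500 * 40
        seq = random_aa_sequence(uniform_profile, n, rng_seed=3)
        se = np.sqrt(0.05 * 0.95 / n)
        for aa in uniform_profile.frequencies:
            assert abs(seq.count(aa) / n - 0.05) < 4 * se

    def test_length_validation(self, uniform_profile):
        with pytest.raises(ValueError):
            random_aa_sequence(uniform_profile, 0, 0)


class TestGenerateMaxent:
    def test_round_trip_and_no_stops(self, table, uniform_profile):
        seqs = generate_maxent(
            uniform_profile, 120, target=0.5, table=table, rng_seed=5, n_sequences=20
        )
        for s in seqs:
            assert len(s.nt) == 3 * len(s.aa)
            assert translate(s.nt, table) == s.aa
            for i in range(0, len(s.nt), 3):
                assert s.nt[i : i + 3] not in table.stop_codons

    def test_single_codon_residues_are_deterministic(self, table):
        seqs = generate_maxent("W" * 100, target=2 / 3, table=table, rng_seed=1)
        assert seqs[0].nt == "TGG" * 100
        assert seqs[0].observed_gc == pytest.approx(2 / 3)
        seqs = generate_maxent("MW", target=0.5, table=table, rng_seed=9)
        assert seqs[0].nt == "ATGTGG"

    def test_exact_sequence_preserved(self, table):
        aa = "MLKFGW" * 10
        seqs = generate_maxent(aa, target=0.5, table=table, rng_seed=2, n_sequences=5)
        for s in seqs:
            assert s.aa == aa

    def test_mean_gc_tracks_target(self, table, uniform_profile):
        for target in (0.35, 0.55):
            seqs = generate_maxent(
                uniform_profile, 500, target=target, table=table,
                rng_seed=8, n_sequences=100,
            )
            gcs = np.array([s.observed_gc for s in seqs])
            se = gcs.std(ddof=1) / np.sqrt(len(gcs))
            assert abs(gcs.mean() - target) < 4 * se

    def test_sd_shrinks_with_length(self, table, uniform_profile):
        sds = {}
        for n in (250, 2500):
            seqs = generate_maxent(
                uniform_profile, n, target=0.5, table=table,
                rng_seed=4, n_sequences=300,
            )
            sds[n] = np.std([s.observed_gc for s in seqs], ddof=1)
        ratio = sds[250] / sds[2500]
        assert ratio == pytest.approx(np.sqrt(10), rel=0.25)

    def test_infeasible_target_propagates(self, table, uniform_profile):
        with pytest.raises(InfeasibleTargetError):
            generate_maxent(uniform_profile, 100, target=0.25, table=table)

    def test_seeded_reproducibility(self, table, uniform_profile):
        a = generate_maxent(uniform_profile, 80, 0.5, table, rng_seed=42, n_sequences=3)
        b = generate_maxent(uniform_profile, 80, 0.5, table, rng_seed=42, n_sequences=3)
        assert [s.nt for s in a] == [s.nt for s in b]

    def test_append_stop_excluded_from_gc(self, table, uniform_profile):
        (s,) = generate_maxent(
            uniform_profile, 50, 0.5, table, rng_seed=6, append_stop=True
        )
        assert s.stop_codon in table.stop_codons
        assert len(s.full_nt) == 3 * 51
        assert s.observed_gc == (s.nt.count("G") + s.nt.count("C")) / 150

    def test_empirical_distribution_matches_enumeration(self, table):
        """For a short fixed protein, empirical GC frequencies match the
        exact codon-combination pmf within Monte-Carlo error."""
        from maxentseq.maxent import solve_beta
        from maxentseq.genetic_code import profile_from_sequence

        aa = "LFG"
        sol = solve_beta(profile_from_sequence(aa), 0.5, table)
        pmf = enumerate_gc_distribution(aa, sol.policy, table)
        n = 100_000
        seqs = generate_maxent(aa, target=0.5, table=table, rng_seed=13, n_sequences=n)
        counts: dict[float, int] = {}
        for s in seqs:
            counts[s.observed_gc] = counts.get(s.observed_gc, 0) + 1
        assert abs(sum(pmf.values()) - 1) < 1e-12
        for gc, p in pmf.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts.get(gc, 0) / n - p) <= 3 * se + 1e-9


class TestGenerateNaive:
    def test_equals_beta_zero_maxent_stream(self, table, uniform_profile):
        naive = generate_naive(uniform_profile, 60, table, rng_seed=21, n_sequences=4)
        g0 = 0.4694444444444445  # uniform-profile expected GC at beta = 0
        maxent = generate_maxent(
            uniform_profile, 60, target=g0, table=table, rng_seed=21, n_sequences=4
        )
        # beta solves to ~0, so the same seed stream gives identical draws
        assert [s.nt for s in naive] == [s.nt for s in maxent]

    def test_degenerate_profile_gc(self, table):
        (s,) = generate_naive(AminoAcidProfile({"W": 1.0}), 30, table, rng_seed=0)
        assert s.observed_gc == pytest.approx(2 / 3)

    def test_mean_gc_near_expectation(self, table, uniform_profile):
        seqs = generate_naive(uniform_profile, 500, table, rng_seed=2, n_sequences=150)
        gcs = np.array([s.observed_gc for s in seqs])
        se = gcs.std(ddof=1) / np.sqrt(len(gcs))
        assert abs(gcs.mean() - 0.4694444) < 4 * se


class TestGenerateRejection:
    def test_accepts_within_window(self, table, uniform_profile):
        s = generate_rejection(
            uniform_profile, 400, gc_lo=0.44, gc_hi=0.50, table=table, rng_seed=3
        )
        assert 0.44 <= s.observed_gc <= 0.50
        assert s.attempts >= 1

    def test_full_window_is_one_naive_draw(self, table, uniform_profile):
        s = generate_rejection(
            uniform_profile, 100, gc_lo=0.0, gc_hi=1.0, table=table, rng_seed=5
        )
        assert s.attempts == 1
        (naive,) = generate_naive(uniform_profile, 100, table, rng_seed=5)
        assert s.nt == naive.nt

    def test_budget_exhaustion(self, table, uniform_profile):
        with pytest.raises(RejectionBudgetError):
            generate_rejection(
                uniform_profile, 2500, gc_lo=0.60, gc_hi=0.61,
                table=table, rng_seed=1, max_attempts=5,
            )

    def test_accepted_gc_skewed_toward_near_bound(self, table, uniform_profile):
        """Window above the naive mean (~0.469): accepted values pile up
        against the lower bound, matching a truncated-Gaussian oracle."""
        accepted = []
        for k in range(150):
            s = generate_rejection(
                uniform_profile, 2500, gc_lo=0.475, gc_hi=0.495,
                table=table, rng_seed=10_000 * k, max_attempts=500,
            )
            accepted.append(s.observed_gc)
        accepted = np.array(accepted)
        mid = 0.485
        # truncated-normal oracle for the same window
        base = generate_naive(
            uniform_profile, 2500, table, rng_seed=77, n_sequences=400
        )
        gcs = np.array([s.observed_gc for s in base])
        trunc = gcs[(gcs >= 0.475) & (gcs <= 0.495)]
        assert (accepted < mid).mean() > 0.5
        assert np.sign(np.median(accepted) - mid) == np.sign(np.median(trunc) - mid)


class TestMultinomial:
    def test_phe_worked_example(self, table):
        pol = multinomial_policy(NucleotideComposition(0.3, 0.3, 0.2, 0.2), table)
        assert pol.probability("F", "TTT") == pytest.approx(0.4, abs=1e-15)
        assert pol.probability("F", "TTC") == pytest.approx(0.6, abs=1e-15)

    def test_uniform_composition_gives_uniform_families(self, table):
        pol = multinomial_policy(NucleotideComposition(0.25, 0.25, 0.25, 0.25), table)
        for aa, fam in table.synonymous_families.items():
            for c in fam:
                assert pol.probability(aa, c) == pytest.approx(1 / len(fam))

    def test_c_rich_phe_probabilities(self, table):
        # 0.2^3 vs 0.2^2 * 0.4 within the two-codon family -> 1/3, 2/3
        pol = multinomial_policy(NucleotideComposition(0.2, 0.4, 0.2, 0.2), table)
        assert pol.probability("F", "TTT") == pytest.approx(1 / 3, abs=1e-15)
        assert pol.probability("F", "TTC") == pytest.approx(2 / 3, abs=1e-15)

    def test_degenerate_composition_rejected(self, table):
        with pytest.raises(DegenerateCompositionError):
            multinomial_policy(NucleotideComposition(0.5, 0.5, 0.0, 0.0), table)

    def test_phe_only_profile_gc(self, table):
        # Phe policy 0.4/0.6 -> expected E per codon 0.6 -> GC 0.2
        seqs = generate_multinomial(
            AminoAcidProfile({"F": 1.0}), 3000,
            target=NucleotideComposition(0.3, 0.3, 0.2, 0.2),
            table=table, rng_seed=4, n_sequences=30,
        )
        gcs = np.array([s.observed_gc for s in seqs])
        se = gcs.std(ddof=1) / np.sqrt(len(gcs))
        assert abs(gcs.mean() - 0.2) < 4 * se

    def test_misses_gc_rich_target(self, table, uniform_profile):
        seqs = generate_multinomial(
            uniform_profile, 1000,
            target=NucleotideComposition(0.3, 0.3, 0.2, 0.2),
            table=table, rng_seed=6, n_sequences=100,
        )
        gcs = np.array([s.observed_gc for s in seqs])
        se = gcs.std(ddof=1) / np.sqrt(len(gcs))
        assert abs(gcs.mean() - 0.60) > 5 * se


class TestGcRange:
    def test_accepts_only_window_and_round_trips(self, table, uniform_profile):
        seqs = generate_gc_range(
            uniform_profile, 800, target=GCTarget.range(0.42, 0.47),
            n_sequences=50, table=table, rng_seed=9,
        )
        assert len(seqs) == 50
        for s in seqs:
            assert 0.42 <= s.observed_gc <= 0.47
            assert translate(s.nt, table) == s.aa

    def test_default_expansion_scale(self):
        # 3 sigma of a binomial GC fraction at the window midpoint
        d = default_expansion(0.40, 0.45, 2500)
        assert d == pytest.approx(3 * np.sqrt(0.425 * 0.575 / 7500), abs=1e-12)

    def test_infeasible_window_raises(self, table, uniform_profile):
        with pytest.raises(InfeasibleTargetError):
            generate_gc_range(
                uniform_profile, 100, target=GCTarget.range(0.05, 0.10),
                n_sequences=1, table=table,
            )

    def test_reproducible(self, table, uniform_profile):
        kw = dict(
            target=GCTarget.range(0.44, 0.48), n_sequences=5,
            table=table, rng_seed=12,
        )
        a = generate_gc_range(uniform_profile, 300, **kw)
        b = generate_gc_range(uniform_profile, 300, **kw)
        assert [s.nt for s in a] == [s.nt for s in b]
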