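"""Consensus, K2P distance, family divergence, identity and copy discovery."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tehop.core_io import Alignment, Sequence
from tehop.family_stats import (
    NoComparableSitesError,
    SaturatedDistanceError,
    TEFamilyObservation,
    build_consensus,
    family_divergence,
    find_copies,
    identity_matrix,
    k2p_distance,
    pairwise_identity,
)
from tehop.synthetic_data import BurstScenario, mutate_sequence, random_ancestor, simulate_burst


def make_pair_with_counts(n_sites, n_ts, n_tv):
    """Aligned pair with exactly the given transition/transversion counts."""
    a = "A" * n_sites
    b = "G" * n_ts + "C" * n_tv + "A" * (n_sites - n_ts - n_tv)
    return Sequence("a", a), Sequence("b", b)


class TestBuildConsensus:
    def test_identical_copies_reproduce_copy(self):
        aln = Alignment([Sequence(f"c{i}", "ACGTACGT") for i in range(3)])
        assert build_consensus(aln).residues == "ACGTACGT"

    def test_hand_evaluated_five_column_toy(self):
        # columns: (A,A,G) (C,C,C) (-,-,T) (G,T,T) (A,N,A); gap threshold 0.5
        # -> A, C, dropped (gap fraction 2/3), T, A => "ACTA"
        aln = Alignment([
            Sequence("s1", "AC-GA"),
            Sequence("s2", "AC-TN"),
            Sequence("s3", "GCTTA"),
        ])
        assert build_consensus(aln, gap_threshold=0.5).residues == "ACTA"

    def test_tie_broken_by_fixed_base_order(self):
        aln = Alignment([
            Sequence("s1", "A"), Sequence("s2", "A"),
            Sequence("s3", "G"), Sequence("s4", "G"),
        ])
        assert build_consensus(aln).residues == "A"

    def test_all_columns_dropped_is_error(self):
        aln = Alignment([Sequence("s1", "--"), Sequence("s2", "--"), Sequence("s3", "AA")])
        with pytest.raises(ValueError, match="no consensus columns"):
            build_consensus(aln, gap_threshold=0.5)

    def test_n_never_wins_a_column(self):
        aln = Alignment([Sequence("s1", "N"), Sequence("s2", "N"), Sequence("s3", "C")])
        assert build_consensus(aln).residues == "C"

    def test_recovers_burst_ancestor(self):
        # >=30 copies at moderate divergence: consensus ~ true ancestor
        sc = BurstScenario(ancestral_length=1000, burst_age=150, copy_count=30, rate=0.001, seed=11)
        res = simulate_burst(sc)
        cons = build_consensus(Alignment(res.copies))
        assert pairwise_identity(cons, res.ancestor, prealigned=True) >= 99.0


class TestK2PDistance:
    def test_identical_sequences(self):
        a = Sequence("a", "ACGT" * 25)
        res = k2p_distance(a, Sequence("b", a.residues))
        assert res == (0.0, 0.0, 0.0, 100)

    def test_closed_form_from_exact_counts(self):
        # 1000 sites, 100 transitions, 50 transversions
        a, b = make_pair_with_counts(1000, 100, 50)
        res = k2p_distance(a, b)
        assert res.P == pytest.approx(0.1) and res.Q == pytest.approx(0.05)
        expected = -0.5 * math.log(1 - 2 * 0.1 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert res.d == pytest.approx(expected, abs=1e-12)
        assert res.d == pytest.approx(0.17018, abs=5e-6)

    def test_saturated_raises(self):
        a, b = make_pair_with_counts(1000, 500, 100)  # P=0.5, Q=0.1 -> log(<=0)
        with pytest.raises(SaturatedDistanceError, match="saturated"):
            k2p_distance(a, b)

    def test_no_comparable_sites_raises(self):
        with pytest.raises(NoComparableSitesError):
            k2p_distance(Sequence("a", "NN--"), Sequence("b", "AC-T"))

    def test_ambiguous_and_gap_columns_excluded(self):
        res = k2p_distance(Sequence("a", "ACGTN-"), Sequence("b", "ACGAN-"))
        assert res.sites == 4 and res.Q == pytest.approx(0.25)  # T<->A is a transversion

    @given(st.integers(0, 40), st.integers(0, 30))
    def test_symmetric_and_dominates_raw_proportion(self, n_ts, n_tv):
        # Kimura correction can only inflate the raw mismatch fraction
        a, b = make_pair_with_counts(200, n_ts, n_tv)
        try:
            fwd = k2p_distance(a, b)
        except SaturatedDistanceError:
            return
        rev = k2p_distance(b, a)
        assert fwd == rev
        assert fwd.d >= (n_ts + n_tv) / 200 - 1e-12

    @pytest.mark.parametrize("d", [0.05, 0.1, 0.2])
    def test_estimator_consistency(self, d):
        # mean estimate over replicates within 2% relative error
        L = 100_000
        rng = np.random.default_rng(500)
        anc = random_ancestor(L, rng)
        est = [k2p_distance(anc, mutate_sequence(anc, d, 2.0, rng)).d for _ in range(10)]
        assert abs(np.mean(est) - d) / d <= 0.02


class TestFamilyDivergence:
    def test_identical_copies(self):
        cons = Sequence("cons", "ACGT" * 25)
        copies = [Sequence(f"c{i}", cons.residues) for i in range(10)]
        mean, sd, n = family_divergence(copies, cons)
        assert (mean, sd, n) == (0.0, 0.0, 10)

    def test_engineered_distances_mean_and_sample_sd(self):
        # copies at exact K2P 0.10 and 0.20 -> 15.0 ± 7.07 (2) in percent
        cons = Sequence("cons", "A" * 1000)

        def copy_at(P, Q, name):
            n_ts, n_tv = int(P * 1000), int(Q * 1000)
            return Sequence(name, "G" * n_ts + "C" * n_tv + "A" * (1000 - n_ts - n_tv))

        # invert: choose pure-transition copies with P giving d exactly
        # d = -1/2 ln(1-2P) for Q=0  =>  P = (1 - exp(-2d))/2
        copies = []
        for i, d in enumerate([0.10, 0.20]):
            P = (1 - math.exp(-2 * d)) / 2
            n_ts = round(P * 1000)
            # denominator 1000 keeps P exact up to the rounding of n_ts;
            # the frozen 15.0/7.07 check below allows for that rounding
            copies.append(copy_at(n_ts / 1000, 0.0, f"c{i}"))
        dvals = [k2p_distance(c, cons).d * 100 for c in copies]
        mean, sd, n = family_divergence(copies, cons)
        assert n == 2
        assert mean == pytest.approx(np.mean(dvals), abs=1e-9)
        assert sd == pytest.approx(np.std(dvals, ddof=1), abs=1e-9)
        # and those equal the hand numbers to the rounding of n_ts
        assert mean == pytest.approx(15.0, abs=0.1)
        assert sd == pytest.approx(7.07, abs=0.1)

    def test_low_coverage_copy_excluded(self):
        cons = Sequence("cons", "A" * 100)
        good = Sequence("good", "A" * 100)
        short = Sequence("short", "A" * 50 + "-" * 50)  # 50% coverage < 0.7
        mean, sd, n = family_divergence([good, short], cons, min_coverage=0.7)
        assert n == 1

    def test_zero_qualifying_copies_is_error(self):
        cons = Sequence("cons", "A" * 100)
        short = Sequence("short", "A" * 10 + "-" * 90)
        with pytest.raises(ValueError, match="qualifying"):
            family_divergence([short], cons, min_coverage=0.7)

    def test_sampling_without_replacement(self, rng):
        cons = Sequence("cons", "ACGT" * 50)
        copies = [Sequence(f"c{i}", cons.residues) for i in range(20)]
        mean, sd, n = family_divergence(copies, cons, sample_size=5, rng=rng)
        assert n == 5


class TestPairwiseIdentity:
    def test_identical(self):
        a = Sequence("a", "ACGTACGT")
        assert pairwise_identity(a, a, prealigned=True) == 100.0

    def test_hand_counted_gapped_pair(self):
        # cols (A,A)(C,C)(G,T)(T,T)(-,T)(A,A): 4 matches / 6 scored
        a = Sequence("a", "ACGT-A")
        b = Sequence("b", "ACTTTA")
        assert pairwise_identity(a, b, prealigned=True) == pytest.approx(400 / 6, abs=1e-9)

    def test_gap_exclude_mode_ignores_gap_columns(self):
        a = Sequence("a", "ACGT-A")
        b = Sequence("b", "ACTTTA")
        assert pairwise_identity(a, b, prealigned=True, mode="gap-exclude") == pytest.approx(80.0)

    def test_gap_gap_columns_ignored(self):
        a = Sequence("a", "AC--GT")
        b = Sequence("b", "AC--GT")
        assert pairwise_identity(a, b, prealigned=True) == 100.0

    def test_empty_overlap_is_error(self):
        with pytest.raises(ValueError, match="overlap"):
            pairwise_identity(Sequence("a", "--NN"), Sequence("b", "--NN"), prealigned=True)

    def test_unaligned_inputs_get_aligned(self):
        a = Sequence("a", "ACGTACGTAC")
        b = Sequence("b", "ACGTCGTAC")  # one deletion
        pid = pairwise_identity(a, b)
        assert pid == pytest.approx(90.0, abs=1e-9)

    def test_identity_matrix_symmetric_with_unit_diagonal(self, rng):
        anc = random_ancestor(300, rng)
        seqs = [("x", anc), ("y", mutate_sequence(anc, 0.05, 2.0, rng)),
                ("z", mutate_sequence(anc, 0.1, 2.0, rng))]
        m = identity_matrix(seqs, prealigned=True)
        assert np.allclose(np.diag(m.values), 100.0)
        assert np.allclose(m.values, m.values.T)


class TestObservation:
    def test_divergence_cell_format(self):
        obs = TEFamilyObservation(
            family="fam", genome="g", consensus=Sequence("c", "ACGT" * 10),
            copy_number=200, divergence_mean=15.0, divergence_sd=2.2, n_sampled=183,
        )
        assert obs.divergence_cell() == "15.0 ± 2 (183)"


class TestFindCopies:
    def test_recovers_planted_exact_copies(self):
        rng = np.random.default_rng(11)
        q = random_ancestor(1000, rng, "q")
        bg = random_ancestor(50_000, rng, "g").residues
        g = bg[:10_000] + q.residues + bg[10_000:30_000] + q.residues + bg[30_000:45_000] + q.residues + bg[45_000:]
        hits = find_copies(Sequence("genome", g), q)
        assert len(hits) == 3
        assert all(h.coverage >= 0.99 and h.identity >= 0.99 for h in hits)

    def test_reverse_strand_hit(self):
        from tehop.family_stats import _revcomp

        rng = np.random.default_rng(13)
        q = random_ancestor(500, rng, "q")
        bg = random_ancestor(20_000, rng, "g").residues
        g = bg[:5000] + _revcomp(q.residues) + bg[5000:]
        hits = find_copies(Sequence("genome", g), q, min_length=100)
        assert len(hits) == 1 and hits[0].strand == "-"

    @pytest.mark.parametrize("seed", range(10))
    def test_random_background_yields_no_hits(self, seed):
        rng = np.random.default_rng(9000 + seed)
        q = random_ancestor(1000, rng, "q")
        g = random_ancestor(100_000, rng, "g")
        assert find_copies(g, q) == []

    def test_mutated_copy_identity_band(self):
        rng = np.random.default_rng(21)
        q = random_ancestor(1000, rng, "q")
        bg = random_ancestor(20_000, rng, "g").residues
        mq = mutate_sequence(q, 0.15, 2.0, rng)
        g = bg[:10_000] + mq.residues + bg[10_000:]
        hits = find_copies(Sequence("genome", g), q)
        assert len(hits) == 1
        assert 0.80 <= hits[0].identity <= 0.90
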