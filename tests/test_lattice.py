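"""Exact lattice inference against the brute-force path enumeration."""

import numpy as np
import pytest
from scipy.special import logsumexp

from porecall import (
    build_duration_model,
    build_kmer_alphabet,
    build_state_space,
    enumerate_bruteforce,
    forced_alignment,
    forward_clamped,
    forward_free,
    occupancy,
    sequence_posterior,
    uniform_shift_transitions,
    viterbi_joint,
)
from porecall.benchmarks import path_log_weight, random_tiny_instance
from porecall.lattice import EnumerationLimitError, LatticeError

from helpers import duration_model_from_weights, random_scores, tiny_state_space


class TestStateSpace:
    def test_intermediate_state_count(self):
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=4, dbar=2)
        assert ss.n_states == ab.size * dm.dbar == 8

    def test_initial_entry_probability(self):
        # alpha=1, uniform xi0 over 4 k-mers, eta(1)=1/2, Dbar=2
        ab = build_kmer_alphabet(1)
        tm = uniform_shift_transitions(ab)
        dm = duration_model_from_weights([0.5, 0.5], gamma=0.0)
        ss = build_state_space(ab, tm, dm, alpha=1.0)
        assert np.exp(ss.arrays.logpi[ss.state_index(0, 1)]) == pytest.approx(0.125)

    def test_tail_self_transition_probability_is_gamma(self):
        gamma = 0.37
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=2, dbar=3, gamma=gamma)
        s = ss.state_index(0, dm.dbar)
        a = ss.arrays
        slot = np.flatnonzero((a.pred_idx[s] == s) & np.isfinite(a.pred_logw[s]))
        assert np.exp(a.pred_logw[s, slot[0]]) == pytest.approx(gamma)

    @pytest.mark.parametrize("alpha", [0.9, 1.0])
    def test_outgoing_probability_mass_is_one(self, alpha):
        for dbar in (1, 2, 3):
            _, _, _, ss = tiny_state_space(k=1, n_bases=4, dbar=dbar, alpha=alpha)
            for state, mass in ss.outgoing_mass().items():
                assert mass == pytest.approx(1.0, abs=1e-12), state

    def test_summary_mentions_counts(self):
        _, _, _, ss = tiny_state_space()
        assert "states=" in ss.summary() and "edges=" in ss.summary()


class TestForwardAgainstEnumeration:
    def test_single_sample_single_path(self):
        # one k-mer, Dbar=1, gamma=0: p(X) must equal phi / |K| (uniform xi0)
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=2, dbar=1, gamma=0.0)
        log_phi = random_scores(1, ab.size, seed=1)
        expected = logsumexp(log_phi[0] + np.log(0.5))
        assert forward_free(log_phi, ss).log_likelihood == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [11, 17, 23, 40, 99])
    def test_forward_matches_enumeration(self, seed):
        log_phi, ss = random_tiny_instance(seed)
        bf = enumerate_bruteforce(log_phi, ss)
        ll = forward_free(log_phi, ss).log_likelihood
        assert ll == pytest.approx(bf.log_px, rel=1e-9)

    @pytest.mark.parametrize("seed", [11, 17, 23])
    def test_clamped_sum_equals_free(self, seed):
        log_phi, ss = random_tiny_instance(seed)
        bf = enumerate_bruteforce(log_phi, ss)
        total = logsumexp(
            [forward_clamped(log_phi, np.array(k), ss).log_likelihood
             for k in bf.log_pkx]
        )
        assert total == pytest.approx(bf.log_px, rel=1e-9)
        for k, ref in bf.log_pkx.items():
            got = forward_clamped(log_phi, np.array(k), ss).log_likelihood
            assert got == pytest.approx(ref, rel=1e-9)

    def test_score_scaling_shifts_log_likelihood(self):
        log_phi, ss = random_tiny_instance(3)
        base = forward_free(log_phi, ss).log_likelihood
        shifted = log_phi.copy()
        shifted[1] += np.log(3.0)  # multiply all scores at one sample by 3
        assert forward_free(shifted, ss).log_likelihood == pytest.approx(
            base + np.log(3.0)
        )

    def test_infeasible_clamped_is_minus_inf(self):
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=2, dbar=2)
        log_phi = random_scores(2, ab.size)
        assert forward_clamped(log_phi, [0, 1, 0], ss).log_likelihood == -np.inf

    def test_m_equals_n_unique_path_closed_form(self):
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=2, dbar=3, gamma=0.2, seed=4)
        log_phi = random_scores(3, ab.size, seed=5)
        kmers = np.array([0, 1, 0])
        expected = (
            np.log(tm.xi0[0])
            + 2 * np.log(tm.xi[0, 1])
            + 3 * np.log(dm.eta[0])
            + log_phi[0, 0]
            + log_phi[1, 1]
            + log_phi[2, 0]
        )
        got = forward_clamped(log_phi, kmers, ss).log_likelihood
        assert got == pytest.approx(expected, rel=1e-12)


class TestViterbi:
    @pytest.mark.parametrize("seed", [2, 7, 13, 29])
    def test_matches_enumeration_argmax(self, seed):
        log_phi, ss = random_tiny_instance(seed)
        bf = enumerate_bruteforce(log_phi, ss)
        vp = viterbi_joint(log_phi, ss)
        assert vp.log_joint == pytest.approx(bf.argmax_log_joint, rel=1e-9)
        audit = path_log_weight(ss, vp.kmers, vp.durations, log_phi)
        assert audit == pytest.approx(bf.argmax_log_joint, rel=1e-9)

    def test_durations_partition_the_read(self):
        log_phi, ss = random_tiny_instance(8)
        vp = viterbi_joint(log_phi, ss)
        assert vp.durations.sum() == log_phi.shape[0]
        assert (vp.durations >= 1).all()

    def test_log_joint_bounded_by_log_likelihood(self):
        log_phi, ss = random_tiny_instance(9)
        vp = viterbi_joint(log_phi, ss)
        assert vp.log_joint <= forward_free(log_phi, ss).log_likelihood + 1e-12


class TestOccupancy:
    @pytest.mark.parametrize("seed", [5, 21])
    def test_rows_sum_to_one(self, seed):
        log_phi, ss = random_tiny_instance(seed)
        occ = occupancy(log_phi, ss)
        np.testing.assert_allclose(occ.gamma.sum(axis=1), 1.0, atol=1e-9)
        assert ((occ.gamma >= 0) & (occ.gamma <= 1 + 1e-12)).all()

    def test_clamped_mass_confined_to_clamped_kmers(self):
        ab, tm, dm, ss = tiny_state_space(k=2, n_bases=2, dbar=2, seed=3)
        log_phi = random_scores(6, ab.size, seed=3)
        kmers = np.array([0, 1])  # AA -> AC
        occ = occupancy(log_phi, ss, kmers)
        np.testing.assert_allclose(occ.gamma.sum(axis=1), 1.0, atol=1e-9)
        absent = np.setdiff1d(np.arange(ab.size), kmers)
        assert (occ.gamma[:, absent] == 0).all()

    def test_matches_pathweighted_bruteforce_posterior(self):
        # |K| = 2, N = 4: average k-mer indicators over all enumerated paths
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=2, dbar=2, gamma=0.25, seed=6)
        n = 4
        log_phi = random_scores(n, ab.size, seed=7)
        from itertools import combinations, product

        weights = []
        visits = []
        for m in range(1, n + 1):
            for seq in product(range(ab.size), repeat=m):
                for cut in combinations(range(1, n), m - 1):
                    bounds = (0,) + cut + (n,)
                    durs = [bounds[i + 1] - bounds[i] for i in range(m)]
                    w = path_log_weight(ss, np.array(seq), np.array(durs), log_phi)
                    lab = np.repeat(seq, durs)
                    weights.append(w)
                    visits.append(lab)
        weights = np.exp(np.array(weights) - logsumexp(weights))
        expected = np.zeros((n, ab.size))
        for w, lab in zip(weights, visits):
            for i, kk in enumerate(lab):
                expected[i, kk] += w
        occ = occupancy(log_phi, ss)
        np.testing.assert_allclose(occ.gamma, expected, atol=1e-9)


class TestForcedAlignment:
    def test_labels_are_ordered_runs_summing_to_n(self):
        ab, tm, dm, ss = tiny_state_space(k=2, n_bases=2, dbar=2, seed=1)
        log_phi = random_scores(9, ab.size, seed=2)
        kmers = np.array([0, 1, 2])  # AA, AC, CA
        labels, durations = forced_alignment(log_phi, kmers, ss)
        assert durations.sum() == 9 and len(labels) == 9
        # exactly M runs in the order of K
        change = np.flatnonzero(np.diff(labels) != 0) + 1
        runs = np.split(labels, change)
        assert [int(r[0]) for r in runs] == kmers.tolist()
        assert [len(r) for r in runs] == durations.tolist()

    def test_matches_clamped_bruteforce_argmax(self):
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=2, dbar=2, gamma=0.3, seed=9)
        n = 5
        log_phi = random_scores(n, ab.size, seed=10)
        kmers = np.array([0, 1])
        from itertools import combinations

        best, best_d = -np.inf, None
        for cut in combinations(range(1, n), 1):
            durs = np.array([cut[0], n - cut[0]])
            w = path_log_weight(ss, kmers, durs, log_phi)
            if w > best:
                best, best_d = w, durs
        _, durations = forced_alignment(log_phi, kmers, ss)
        assert durations.tolist() == best_d.tolist()

    def test_infeasible_alignment_raises(self):
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=2, dbar=2)
        log_phi = random_scores(2, ab.size)
        with pytest.raises(LatticeError):
            forced_alignment(log_phi, np.array([0, 1, 0]), ss)

    def test_durations_can_exceed_dbar(self):
        # the tail self-loop reports true dwell lengths, not capped at Dbar
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=2, dbar=2, gamma=0.5, seed=2)
        log_phi = random_scores(7, ab.size, seed=3)
        _, durations = forced_alignment(log_phi, np.array([1]), ss)
        assert durations.tolist() == [7]


class TestSequencePosterior:
    def test_posteriors_sum_to_one_over_enumerable_sequences(self):
        log_phi, ss = random_tiny_instance(14)
        bf = enumerate_bruteforce(log_phi, ss)
        total = sum(sequence_posterior(log_phi, np.array(k), ss) for k in bf.log_pkx)
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_equals_forward_ratio(self):
        log_phi, ss = random_tiny_instance(15)
        bf = enumerate_bruteforce(log_phi, ss)
        k = next(iter(bf.log_pkx))
        expected = np.exp(
            forward_clamped(log_phi, np.array(k), ss).log_likelihood
            - forward_free(log_phi, ss).log_likelihood
        )
        assert sequence_posterior(log_phi, np.array(k), ss) == pytest.approx(expected)


class TestBruteForce:
    def test_path_count(self):
        # full-support k=1 chain over 2 bases: sum_M 2 * 2^(M-1) * C(N-1, M-1)
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=2, dbar=2)
        n = 5
        log_phi = random_scores(n, ab.size)
        bf = enumerate_bruteforce(log_phi, ss)
        from math import comb

        expected = sum(2 * 2 ** (m - 1) * comb(n - 1, m - 1) for m in range(1, n + 1))
        assert bf.n_paths == expected

    def test_duration_compositions_count(self):
        # M=3 k-mers over N=5 samples admit C(4,2)=6 duration assignments
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=2, dbar=2)
        log_phi = random_scores(5, ab.size)
        bf = enumerate_bruteforce(log_phi, ss)
        seqs3 = [k for k in bf.log_pkx if len(k) == 3]
        assert len(seqs3) == 2 * 2 * 2  # binary chain, full support
        # count paths for one such sequence by re-enumerating durations
        from itertools import combinations

        assert len(list(combinations(range(1, 5), 2))) == 6

    def test_limit_guard(self):
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=4, dbar=2)
        log_phi = random_scores(7, ab.size)
        with pytest.raises(EnumerationLimitError):
            enumerate_bruteforce(log_phi, ss, limit=10)


def test_empty_scores_rejected():
    _, _, _, ss = tiny_state_space()
    with pytest.raises(LatticeError):
        forward_free(np.empty((0, 2)), ss)
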