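"""Training gradients, EM fitting, and scorer pre-training."""

import numpy as np
import pytest

from porecall import (
    GaussianObservation,
    LabeledSamples,
    RbfSoftmaxScorer,
    SimulatorConfig,
    TrainingConfig,
    build_duration_model,
    build_kmer_alphabet,
    build_state_space,
    cml_train_gaussian_means,
    fit_gaussian_em,
    modified_cml_loss,
    pretrain_scorer,
    score_gradients,
    simulate_run,
    synthetic_pore_model,
    uniform_shift_transitions,
)
from porecall.benchmarks import _fd_gradient, random_tiny_instance
from porecall.models import ModelError, ReadRecord
from porecall.lattice import forward_clamped, forward_free, LatticeError

from helpers import random_scores, tiny_state_space


def _feasible_sequence(ss, rng, m):
    ab = ss.alphabet
    k = [int(rng.integers(ab.size))]
    for _ in range(m - 1):
        k.append(int(rng.choice(ab.successors(k[-1]))))
    return np.array(k)


class TestScoreGradients:
    @pytest.mark.parametrize("seed", [3, 11])
    def test_free_running_matches_finite_differences(self, seed):
        log_phi, ss = random_tiny_instance(seed)
        res = score_gradients(log_phi, ss)
        fd = _fd_gradient(lambda lp: forward_free(lp, ss).log_likelihood, log_phi)
        np.testing.assert_allclose(res.d_logphi, fd, rtol=1e-5, atol=1e-7)

    def test_clamped_matches_finite_differences(self):
        log_phi, ss = random_tiny_instance(6)
        rng = np.random.default_rng(6)
        kmers = _feasible_sequence(ss, rng, 2)
        res = score_gradients(log_phi, ss, kmers)
        fd = _fd_gradient(
            lambda lp: forward_clamped(lp, kmers, ss).log_likelihood, log_phi
        )
        np.testing.assert_allclose(res.d_logphi, fd, rtol=1e-5, atol=1e-7)

    def test_free_gradient_rows_sum_to_one(self):
        log_phi, ss = random_tiny_instance(7)
        res = score_gradients(log_phi, ss)
        np.testing.assert_allclose(res.d_logphi.sum(axis=1), 1.0, atol=1e-9)

    def test_clamped_gradient_zero_off_support(self):
        ab, tm, dm, ss = tiny_state_space(k=2, n_bases=2, dbar=2, seed=5)
        log_phi = random_scores(5, ab.size, seed=5)
        kmers = np.array([0, 1])
        res = score_gradients(log_phi, ss, kmers)
        absent = np.setdiff1d(np.arange(ab.size), kmers)
        assert (res.d_logphi[:, absent] == 0).all()

    def test_zero_likelihood_raises(self):
        ab, tm, dm, ss = tiny_state_space(k=1, n_bases=2, dbar=2)
        log_phi = random_scores(2, ab.size)
        with pytest.raises(LatticeError):
            score_gradients(log_phi, ss, np.array([0, 1, 0]))  # M > N


class TestModifiedCml:
    def test_lambda_one_reduces_to_clamped(self):
        log_phi, ss = random_tiny_instance(8)
        rng = np.random.default_rng(8)
        kmers = _feasible_sequence(ss, rng, 2)
        res = modified_cml_loss(log_phi, kmers, ss, TrainingConfig(lam=1.0))
        clamped = score_gradients(log_phi, ss, kmers)
        assert res.loss == pytest.approx(clamped.loss)
        np.testing.assert_allclose(res.d_logphi, clamped.d_logphi, atol=1e-12)

    def test_beam_variant_with_matching_decode_scales_loss(self):
        log_phi, ss = random_tiny_instance(10)
        rng = np.random.default_rng(10)
        kmers = _feasible_sequence(ss, rng, 2)
        lam = 0.5
        cfg = TrainingConfig(lam=lam, variant="beam")
        res = modified_cml_loss(log_phi, kmers, ss, cfg, kmers_bs=kmers)
        ref = score_gradients(log_phi, ss, kmers)
        assert res.loss == pytest.approx(lam * ref.loss)

    @pytest.mark.parametrize("variant", ["free_running", "beam"])
    def test_half_lambda_gradients_match_finite_differences(self, variant):
        log_phi, ss = random_tiny_instance(12)
        rng = np.random.default_rng(12)
        kmers = _feasible_sequence(ss, rng, 2)
        cfg = TrainingConfig(lam=0.5, variant=variant, beams=8)
        kmers_bs = None
        if variant == "beam":
            from porecall import GMBSConfig, gmbs_decode

            kmers_bs, _ = gmbs_decode(log_phi, ss, GMBSConfig(beams=8))
        res = modified_cml_loss(log_phi, kmers, ss, cfg, kmers_bs=kmers_bs)
        fd = _fd_gradient(
            lambda lp: modified_cml_loss(lp, kmers, ss, cfg, kmers_bs=kmers_bs).loss,
            log_phi,
        )
        np.testing.assert_allclose(res.d_logphi, fd, rtol=1e-5, atol=1e-7)


def _em_setup(n_reads=30, seed=2):
    ab = build_kmer_alphabet(2)
    tm = uniform_shift_transitions(ab)
    dm = build_duration_model(5.0, 4.0, 8)
    obs = synthetic_pore_model(ab, sigma=0.08)
    cfg = SimulatorConfig(ab, tm, dm, obs, fixed_m=40, noise_scale=1.0)
    reads = simulate_run(cfg, n_reads, seed)
    ss = build_state_space(ab, tm, dm)
    return ab, obs, reads, ss


class TestGaussianEm:
    def test_likelihood_monotone_and_means_recovered(self):
        ab, obs, reads, ss = _em_setup()
        refs = [r.truth_kmers for r in reads]
        init = GaussianObservation(mu=np.zeros(ab.size), sigma=np.ones(ab.size))
        fitted, trace = fit_gaussian_em(
            reads, refs, init, ss, TrainingConfig(max_iter=6, tol=1e-9)
        )
        trace = np.array(trace)
        assert (np.diff(trace) >= -1e-8 * np.abs(trace[:-1])).all()
        dyn = obs.mu.max() - obs.mu.min()
        assert np.max(np.abs(fitted.mu - obs.mu)) < 0.05 * dyn

    def test_constant_single_kmer_read_closed_form(self):
        ab = build_kmer_alphabet(1, ("A", "C"))
        tm = uniform_shift_transitions(ab)
        dm = build_duration_model(3.0, 3.0, 4, 0.2)
        ss = build_state_space(ab, tm, dm)
        read = ReadRecord(signal=np.full(6, 1.7))
        init = GaussianObservation(mu=np.array([0.0, 5.0]), sigma=np.ones(2))
        fitted, trace = fit_gaussian_em(
            [read], [np.array([0])], init, ss, TrainingConfig(max_iter=3)
        )
        assert fitted.mu[0] == pytest.approx(1.7)
        assert fitted.sigma[0] == pytest.approx(1e-3)  # floored
        # the never-visited k-mer keeps its initial parameters
        assert fitted.mu[1] == 5.0 and fitted.sigma[1] == 1.0

    def test_mismatched_references_rejected(self):
        ab, obs, reads, ss = _em_setup(n_reads=2)
        with pytest.raises(ModelError):
            fit_gaussian_em(reads, [reads[0].truth_kmers], obs, ss)


class TestPretrain:
    def _labelled_zero_noise(self, n_reads=10, seed=3):
        ab = build_kmer_alphabet(2)
        tm = uniform_shift_transitions(ab)
        dm = build_duration_model(5.0, 4.0, 8)
        obs = synthetic_pore_model(ab, sigma=0.08)
        cfg = SimulatorConfig(ab, tm, dm, obs, fixed_m=40, noise_scale=1e-3)
        reads = simulate_run(cfg, n_reads, seed)
        signals = [r.signal for r in reads]
        labels = [np.repeat(r.truth_kmers, r.truth_durations) for r in reads]
        return ab, signals, labels

    def test_loss_decreases_and_accuracy_high_on_separable_data(self):
        ab, signals, labels = self._labelled_zero_noise()
        data = LabeledSamples(signals=signals, labels=labels)
        scorer = RbfSoftmaxScorer.from_signal_range(ab.size, signals, seed=0)
        scorer, trace = pretrain_scorer(
            data, scorer, TrainingConfig(max_iter=300, tol=0.0, learning_rate=2.0)
        )
        assert trace[-1] < trace[0]
        assert (np.diff(trace) <= 1e-9).all()  # non-increasing
        correct = total = 0
        for x, y in zip(signals, labels):
            correct += (scorer.log_scores(x).argmax(axis=1) == y).sum()
            total += len(y)
        assert correct / total > 0.9

    def test_near_one_hot_scorer_has_near_zero_loss(self):
        ab, signals, labels = self._labelled_zero_noise(n_reads=2)
        # a scorer pre-trained to convergence on separable data emits nearly
        # one-hot-correct scores, so its cross-entropy approaches zero
        data = LabeledSamples(signals=signals, labels=labels)
        scorer = RbfSoftmaxScorer.from_signal_range(ab.size, signals, n_centers=48)
        scorer, trace = pretrain_scorer(
            data, scorer, TrainingConfig(max_iter=800, tol=0.0, learning_rate=3.0)
        )
        assert trace[-1] < 0.25

    def test_length_mismatch_rejected(self):
        with pytest.raises(ModelError):
            LabeledSamples(signals=[np.zeros(3)], labels=[np.zeros(4, dtype=int)])


def test_cml_objective_improves_over_gradient_steps():
    """30 ascent steps on the per-k-mer means strictly improve the modified
    CML objective of a fixed simulated batch."""
    ab = build_kmer_alphabet(2)
    tm = uniform_shift_transitions(ab)
    dm = build_duration_model(4.0, 4.0, 6)
    obs = synthetic_pore_model(ab, sigma=0.15)
    cfg = SimulatorConfig(ab, tm, dm, obs, fixed_m=15, noise_scale=1.5)
    reads = simulate_run(cfg, 5, seed=9)
    refs = [r.truth_kmers for r in reads]
    ss = build_state_space(ab, tm, dm)
    # start from a perturbed table so there is room to improve
    rng = np.random.default_rng(1)
    start = GaussianObservation(
        mu=obs.mu + rng.normal(scale=0.3, size=ab.size), sigma=obs.sigma
    )
    _, trace = cml_train_gaussian_means(
        reads, refs, start, ss, TrainingConfig(lam=0.5), n_steps=30, step_size=3e-4
    )
    assert len(trace) == 30
    assert trace[-1] > trace[0]
    # most of the improvement arrives early and is never fully given back
    assert max(trace) - trace[-1] < 0.1 * (trace[-1] - trace[0])
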