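"""Training: conditional-maximum-likelihood gradients, EM, pre-training.

The trainable part of the basecaller is the observation scorer phi[n, K].
Because the lattice log-likelihoods are linear in each log-score along any
path, their gradients are posterior visit probabilities (occupancies):

    d log p(X)    / d log phi[n, K] = p(K_n = K | X)        (free-running)
    d log p(K, X) / d log phi[n, K] = p(K_n = K | X, K)     (clamped)

The modified CML objective regularizes the vanilla conditional likelihood
log p(K|X) = log p(K,X) - log p(X) to stop the scorer from simply driving
log p(X) down:

    free-running variant:  log p(K, X) - (1 - lambda) * log p(X)
    beam variant:          log p(K, X) - (1 - lambda) * log p(K_bs, X)

with lambda = 1/2 by default, where K_bs is the beam-search decode of the
read and both terms of the beam variant use clamped lattices.  The beam
variant focuses learning on reads where the decoder still disagrees with
the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax

from .gmbs import DecodeError, GMBSConfig, gmbs_decode
from .lattice import (
    LatticeError,
    StateSpace,
    forward_clamped,
    forward_free,
    occupancy,
)
from .models import GaussianObservation, ModelError, ReadRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "GradientResult",
    "LabeledSamples",
    "score_gradients",
    "modified_cml_loss",
    "fit_gaussian_em",
    "RbfSoftmaxScorer",
    "pretrain_scorer",
    "cml_train_gaussian_means",
]

SIGMA_FLOOR = 1e-3  # signal units; prevents degenerate EM variances


@dataclass(frozen=True)
class TrainingConfig:
    """Shared knobs for the training entry points."""

    lam: float = 0.5  # regularization factor lambda in [0, 1]
    variant: str = "free_running"  # or "beam"
    beams: int = 64
    max_iter: int = 25
    tol: float = 1e-6
    seed: int = 0
    learning_rate: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ModelError("lambda must lie in [0, 1]")
        if self.variant not in ("free_running", "beam"):
            raise ModelError(f"unknown CML variant {self.variant!r}")


@dataclass(frozen=True)
class GradientResult:
    """Objective value and its gradient with respect to the log-scores."""

    loss: float
    d_logphi: np.ndarray  # (N, |K|)


@dataclass(frozen=True)
class LabeledSamples:
    """Per-sample k-mer labels (e.g. from forced alignment) with signals."""

    signals: list[np.ndarray]
    labels: list[np.ndarray]

    def __post_init__(self):
        if len(self.signals) != len(self.labels):
            raise ModelError("signals and labels must pair up")
        for x, y in zip(self.signals, self.labels):
            if len(x) != len(y):
                raise ModelError("label length must equal signal length per read")


def score_gradients(log_phi: np.ndarray, ss: StateSpace, kmers=None) -> GradientResult:
    """Gradient of log p(X) (or log p(K, X) when ``kmers`` is given) with
    respect to the log-scores: exactly the occupancy matrix."""
    if kmers is None:
        ll = forward_free(log_phi, ss).log_likelihood
    else:
        ll = forward_clamped(log_phi, kmers, ss).log_likelihood
    if not np.isfinite(ll):
        raise LatticeError("zero-likelihood read: gradient undefined")
    occ = occupancy(log_phi, ss, kmers)
    return GradientResult(loss=float(ll), d_logphi=occ.gamma)


def modified_cml_loss(
    log_phi: np.ndarray,
    kmers,
    ss: StateSpace,
    cfg: TrainingConfig = TrainingConfig(),
    kmers_bs=None,
) -> GradientResult:
    """Modified CML objective and its log-score gradient.

    For the beam variant, ``kmers_bs`` (the decoded sequence) is treated as
    a constant of the objective; when omitted it is computed here with
    ``cfg.beams`` beams.  A decode failure falls back to the free-running
    variant with a logged warning.
    """
    ref = score_gradients(log_phi, ss, kmers)
    variant = cfg.variant
    if variant == "beam" and kmers_bs is None:
        try:
            kmers_bs, _ = gmbs_decode(log_phi, ss, GMBSConfig(beams=cfg.beams))
        except DecodeError:
            logger.warning("beam decode failed; falling back to free-running CML")
            variant = "free_running"
    if variant == "beam":
        other = score_gradients(log_phi, ss, kmers_bs)
    else:
        other = score_gradients(log_phi, ss)
    loss = ref.loss - (1.0 - cfg.lam) * other.loss
    grad = ref.d_logphi - (1.0 - cfg.lam) * other.d_logphi
    return GradientResult(loss=float(loss), d_logphi=grad)


# ---------------------------------------------------------------------------
# Baum-Welch fitting of the Gaussian alignment model


def fit_gaussian_em(
    reads: list[ReadRecord],
    references: list[np.ndarray],
    init: GaussianObservation,
    ss_template: StateSpace,
    cfg: TrainingConfig = TrainingConfig(),
) -> tuple[GaussianObservation, list[float]]:
    """EM for the per-k-mer Gaussian table used in forced alignment.

    E-step: clamped occupancies of each read against its reference k-mer
    sequence; M-step: occupancy-weighted means and variances per k-mer,
    with sigma floored at 1e-3 signal units.  K-mers never visited keep
    their initial parameters (logged once).  Returns the fitted table and
    the per-iteration total clamped log-likelihood trace (non-decreasing).
    """
    if len(reads) != len(references):
        raise ModelError("each read needs a reference k-mer sequence")
    obs = init
    nk = ss_template.alphabet.size
    trace: list[float] = []
    ss = ss_template  # the lattice itself carries no emission parameters
    for _ in range(cfg.max_iter):
        total_ll = 0.0
        wsum = np.zeros(nk)
        wx = np.zeros(nk)
        wxx = np.zeros(nk)
        for read, ref in zip(reads, references):
            log_phi = obs.log_scores(read.signal)
            g = score_gradients(log_phi, ss, ref)
            total_ll += g.loss
            occ = g.d_logphi  # clamped occupancy, (N, nk)
            wsum += occ.sum(axis=0)
            wx += occ.T @ read.signal
            wxx += occ.T @ (read.signal**2)
        trace.append(total_ll)
        visited = wsum > 1e-12
        if not visited.all():
            logger.info("%d k-mers never visited; keeping init", int((~visited).sum()))
        mu = np.where(visited, wx / np.where(visited, wsum, 1.0), obs.mu)
        var = np.where(
            visited, wxx / np.where(visited, wsum, 1.0) - mu**2, obs.sigma**2
        )
        sigma = np.sqrt(np.maximum(var, SIGMA_FLOOR**2))
        obs = GaussianObservation(mu=mu, sigma=sigma)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(trace[-1] - prev) <= cfg.tol * max(1.0, abs(prev)):
                break
    return obs, trace


# ---------------------------------------------------------------------------
# pluggable trainable scorer + cross-entropy pre-training


class RbfSoftmaxScorer:
    """Softmax regression on Gaussian radial-basis features of each sample.

    A deliberately small stand-in for a neural match network: the feature
    map is fixed (RBF bumps spanning the signal range plus a bias), only the
    weight matrix W (n_features x |K|) is trained.  ``log_scores`` returns
    log-softmax outputs, which are strictly positive scores after
    exponentiation, so the object satisfies the ObservationScorer contract.
    """

    def __init__(self, n_kmers: int, centers: np.ndarray, width: float, seed: int = 0):
        self.centers = np.asarray(centers, dtype=float)
        self.width = float(width)
        rng = np.random.default_rng(seed)
        self.weights = 0.01 * rng.standard_normal((self.centers.size + 1, n_kmers))

    @classmethod
    def from_signal_range(
        cls, n_kmers: int, signals: list[np.ndarray], n_centers: int = 32, seed: int = 0
    ) -> "RbfSoftmaxScorer":
        lo = min(float(np.min(x)) for x in signals)
        hi = max(float(np.max(x)) for x in signals)
        centers = np.linspace(lo, hi, n_centers)
        width = (hi - lo) / max(n_centers - 1, 1)
        return cls(n_kmers, centers, width, seed=seed)

    def design_matrix(self, signal: np.ndarray) -> np.ndarray:
        x = np.asarray(signal, dtype=float)
        rbf = np.exp(-0.5 * ((x[:, None] - self.centers[None, :]) / self.width) ** 2)
        return np.hstack([rbf, np.ones((x.size, 1))])

    def log_scores(self, signal: np.ndarray) -> np.ndarray:
        return log_softmax(self.design_matrix(signal) @ self.weights, axis=1)


def pretrain_scorer(
    data: LabeledSamples, scorer: RbfSoftmaxScorer, cfg: TrainingConfig = TrainingConfig()
) -> tuple[RbfSoftmaxScorer, list[float]]:
    """Per-sample cross-entropy pre-training against one-hot k-mer labels.

    Full-batch gradient descent on the softmax-regression weights; returns
    the scorer and the per-epoch mean cross-entropy trace.
    """
    X = np.vstack([scorer.design_matrix(x) for x in data.signals])
    y = np.concatenate([np.asarray(l, dtype=np.int64) for l in data.labels])
    n, nk = X.shape[0], scorer.weights.shape[1]
    onehot = np.zeros((n, nk))
    onehot[np.arange(n), y] = 1.0
    trace: list[float] = []
    lr = cfg.learning_rate
    for _ in range(cfg.max_iter):
        p = softmax(X @ scorer.weights, axis=1)
        ce = float(-np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-300))))
        trace.append(ce)
        grad = X.T @ (p - onehot) / n
        scorer.weights = scorer.weights - lr * grad
        if len(trace) >= 2 and trace[-2] - trace[-1] < cfg.tol:
            break
    return scorer, trace


# ---------------------------------------------------------------------------
# toy end-to-end CML training of a parametric scorer


def cml_train_gaussian_means(
    reads: list[ReadRecord],
    references: list[np.ndarray],
    obs: GaussianObservation,
    ss_template: StateSpace,
    cfg: TrainingConfig = TrainingConfig(),
    n_steps: int = 30,
    step_size: float = 0.05,
) -> tuple[GaussianObservation, list[float]]:
    """Gradient ascent of the modified CML objective over the per-k-mer means.

    The chain rule through the Gaussian log-score gives
    d log phi[n, K] / d mu_K = (x_n - mu_K) / sigma_K**2, so the mean update
    aggregates the occupancy-combination gradient over samples.  Returns the
    updated table and the per-step total objective trace.
    """
    trace: list[float] = []
    mu = obs.mu.copy()
    for _ in range(n_steps):
        cur = GaussianObservation(mu=mu, sigma=obs.sigma)
        total = 0.0
        grad_mu = np.zeros_like(mu)
        for read, ref in zip(reads, references):
            log_phi = cur.log_scores(read.signal)
            res = modified_cml_loss(log_phi, ref, ss_template, cfg)
            total += res.loss
            resid = (read.signal[:, None] - mu[None, :]) / (obs.sigma[None, :] ** 2)
            grad_mu += (res.d_logphi * resid).sum(axis=0)
        trace.append(total)
        mu = mu + step_size * grad_mu
    return GaussianObservation(mu=mu, sigma=obs.sigma), trace
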