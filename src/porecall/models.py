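"""Transition, dwell-time, and observation models of the duration HMM.

Three ingredients parameterize the generative model of a nanopore read:

* a first-order Markov chain over k-mers (initial distribution ``xi0`` and
  row-stochastic matrix ``xi``, supported on single-base shifts),
* an explicit dwell-time distribution ``eta(d)`` over d = 1..Dbar with a
  geometric tail of factor ``gamma`` beyond the maximum explicit duration
  Dbar, i.e. eta(Dbar + m) = gamma**m * eta(Dbar),
* per-sample observation scores ``phi[n, K]`` — either a per-k-mer Gaussian
  table or any pluggable scorer mapping a signal of length N to an
  N x |K| table of strictly positive scores.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import stats

from .alphabet import KmerAlphabet, kmers_from_sequence

__all__ = [
    "TransitionModel",
    "DurationModel",
    "ObservationScorer",
    "GaussianObservation",
    "ReadRecord",
    "uniform_shift_transitions",
    "count_transitions_from_reference",
    "build_duration_model",
    "estimate_duration_scale",
    "gaussian_scores",
]

_ATOL = 1e-12


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# transitions


@dataclass(frozen=True)
class TransitionModel:
    """Markov chain over k-mers: initial ``xi0`` and transition matrix ``xi``."""

    alphabet: KmerAlphabet
    xi0: np.ndarray  # (|K|,)
    xi: np.ndarray  # (|K|, |K|) row-stochastic

    def __post_init__(self):
        n = self.alphabet.size
        if self.xi0.shape != (n,) or self.xi.shape != (n, n):
            raise ModelError("transition model shape mismatch with alphabet")
        if not np.isclose(self.xi0.sum(), 1.0, atol=1e-9):
            raise ModelError("xi0 must sum to 1")
        if not np.allclose(self.xi.sum(axis=1), 1.0, atol=1e-9):
            raise ModelError("every row of xi must sum to 1")
        if (self.xi0 < 0).any() or (self.xi < 0).any():
            raise ModelError("transition probabilities must be non-negative")

    def log_xi0(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.xi0)

    def log_xi(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.xi)

    def successor_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Padded per-row lists of successors with nonzero probability.

        Returns ``(succ, logp)`` of shape (|K|, width); padding entries have
        successor 0 and log-probability -inf.
        """
        rows = [np.flatnonzero(r) for r in self.xi]
        width = max(1, max(len(r) for r in rows))
        succ = np.zeros((self.alphabet.size, width), dtype=np.int64)
        logp = np.full((self.alphabet.size, width), -np.inf)
        for i, r in enumerate(rows):
            succ[i, : len(r)] = r
            logp[i, : len(r)] = np.log(self.xi[i, r])
        return succ, logp


def uniform_shift_transitions(
    alphabet: KmerAlphabet, self_loops: bool = True
) -> TransitionModel:
    """Genome-agnostic transitions: uniform over single-base shifts.

    Each k-mer moves to one of its ``|bases|`` shift successors with equal
    probability (1/4 for DNA); all other transitions have probability zero.
    ``xi0`` is uniform.  With ``self_loops=False`` the homopolymer
    self-successor (e.g. AAA -> AAA) is removed and the remaining successors
    renormalized — this yields signals in which dwell time is never
    confounded with homopolymer length, used for unambiguous-regime tests.
    """
    n = alphabet.size
    xi = np.zeros((n, n))
    for kmer in range(n):
        succ = alphabet.successors(kmer)
        if not self_loops:
            succ = succ[succ != kmer]
        xi[kmer, succ] = 1.0 / len(succ)
    return TransitionModel(alphabet, np.full(n, 1.0 / n), xi)


def count_transitions_from_reference(
    seq: str, alphabet: KmerAlphabet, pseudocount: float = 0.0
) -> TransitionModel:
    """Maximum-likelihood (frequency counting) transition estimate.

    Counts one-base-shift k-mer bigrams in a reference sequence; the
    pseudocount is added on the shift support only.  Rows that remain all
    zero fall back to the uniform-shift distribution.  ``xi0`` is uniform.
    """
    if len(seq) < alphabet.k + 1:
        raise ModelError("reference sequence too short to count transitions")
    if pseudocount < 0:
        raise ModelError("pseudocount must be non-negative")
    path = kmers_from_sequence(seq, alphabet)
    n = alphabet.size
    counts = np.zeros((n, n))
    np.add.at(counts, (path[:-1], path[1:]), 1.0)
    xi = np.zeros((n, n))
    for kmer in range(n):
        succ = alphabet.successors(kmer)
        row = counts[kmer, succ] + pseudocount
        total = row.sum()
        xi[kmer, succ] = row / total if total > 0 else 1.0 / len(succ)
    return TransitionModel(alphabet, np.full(n, 1.0 / n), xi)


# ---------------------------------------------------------------------------
# dwell times


@dataclass(frozen=True)
class DurationModel:
    """Explicit dwell distribution with a geometric tail.

    ``eta[d-1]`` holds eta(d) for d = 1..Dbar.  The implied full pmf is
    eta(d) for d < Dbar and eta(Dbar) * gamma**(d - Dbar) for d >= Dbar, so
    total mass is sum_{d<Dbar} eta(d) + eta(Dbar)/(1-gamma) = 1.

    ``loglogistic`` optionally records the continuous (scale a, shape b)
    the table was discretized from, enabling per-read rescaling of the mean
    dwell via ``scale`` (the scale parameter a is multiplied, so the mean is
    proportional to ``scale``).
    """

    eta: np.ndarray
    gamma: float
    scale: float = 1.0
    loglogistic: tuple[float, float] | None = None

    def __post_init__(self):
        if not 0.0 <= self.gamma < 1.0:
            raise ModelError(f"tail factor gamma must be in [0, 1), got {self.gamma}")
        if (self.eta < 0).any():
            raise ModelError("eta entries must be non-negative")
        total = self.eta[:-1].sum() + self.eta[-1] / (1.0 - self.gamma)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ModelError(f"duration mass is {total}, expected 1")
        if self.scale <= 0:
            raise ModelError("duration scale must be positive")

    @property
    def dbar(self) -> int:
        return len(self.eta)

    def entry_probs(self) -> np.ndarray:
        """Probability of entering duration state d = 1..Dbar.

        The Dbar entry absorbs the whole geometric tail: eta(Dbar)/(1-gamma).
        These sum to 1 and are the reset weights used on the lattice.
        """
        p = self.eta.copy()
        p[-1] /= 1.0 - self.gamma
        return p

    def pmf(self, d) -> np.ndarray:
        """Actual dwell pmf, tail expanded analytically."""
        d = np.asarray(d, dtype=np.int64)
        out = np.zeros(d.shape, dtype=float)
        short = (d >= 1) & (d < self.dbar)
        out[short] = self.eta[d[short] - 1]
        tail = d >= self.dbar
        out[tail] = self.eta[-1] * self.gamma ** (d[tail] - self.dbar)
        return out

    def mean(self) -> float:
        d = np.arange(1, self.dbar)
        head = float((d * self.eta[:-1]).sum())
        g = self.gamma
        return head + self.eta[-1] * (self.dbar / (1 - g) + g / (1 - g) ** 2)

    def rescaled(self, scale: float) -> "DurationModel":
        """Per-read variant with the log-logistic scale multiplied by ``scale``."""
        if self.loglogistic is None:
            raise ModelError("rescaling requires log-logistic parameters")
        a, b = self.loglogistic
        m = build_duration_model(a * scale, b, self.dbar, self.gamma)
        return replace(m, scale=scale)


def _loglogistic_cdf(x, a: float, b: float):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = 1.0 / (1.0 + (x[pos] / a) ** (-b))
    return out


def _loglogistic_mean(a: float, b: float) -> float:
    if b <= 1:
        raise ModelError(f"log-logistic mean is infinite for shape b={b} <= 1")
    t = np.pi / b
    return a * t / np.sin(t)


def build_duration_model(
    a: float, b: float, dbar: int, gamma: float | str = "mean-matched"
) -> DurationModel:
    """Discretize a log-logistic dwell law onto 1..Dbar with a geometric tail.

    eta(d) for d < Dbar is the continuous CDF mass on (d-1/2, d+1/2]
    (lower edge clipped at 0); eta(Dbar) takes whatever mass remains, spread
    over the tail: eta(Dbar) = (1 - sum_{d<Dbar} eta(d)) * (1 - gamma).

    ``gamma="mean-matched"`` solves for the tail factor that makes the model
    mean equal the continuous log-logistic mean (requires shape b > 1), so
    the truncation preserves a representative mean dwell time.
    """
    if a <= 0 or b <= 0:
        raise ModelError("log-logistic parameters must be positive")
    if dbar < 1:
        raise ModelError("Dbar must be a positive integer")
    d = np.arange(1, dbar, dtype=float)
    head = _loglogistic_cdf(d + 0.5, a, b) - _loglogistic_cdf(np.maximum(d - 0.5, 0.0), a, b)
    residual = 1.0 - head.sum()  # mass at and beyond Dbar
    if residual <= 0:
        raise ModelError("Dbar too large: no residual tail mass")

    if isinstance(gamma, str):
        if gamma != "mean-matched":
            raise ModelError(f"unknown gamma mode {gamma!r}")
        target = _loglogistic_mean(a, b)
        # model mean = sum_{d<Dbar} d*eta(d) + residual*(Dbar + gamma/(1-gamma))
        t = (target - float((d * head).sum()) - residual * dbar) / residual
        gamma = max(0.0, t / (1.0 + t)) if t > -1 else 0.0
    gamma = float(gamma)
    if not 0.0 <= gamma < 1.0:
        raise ModelError(f"tail factor gamma must be in [0, 1), got {gamma}")

    eta = np.concatenate([head, [residual * (1.0 - gamma)]])
    return DurationModel(eta=eta, gamma=gamma, loglogistic=(a, b))


def estimate_duration_scale(
    signal,
    change_threshold: float = 4.0,
    clip: tuple[float, float] = (1.0, 50.0),
) -> float:
    """Estimate a read's mean dwell from the rate of large signal changes.

    Counts sample-to-sample differences exceeding ``change_threshold`` times
    the read's robust spread (median absolute deviation of the differences,
    scaled to Gaussian sigma); each such jump is taken as one k-mer boundary,
    so the mean dwell estimate is N / max(count, 1), clipped to ``clip``.
    Divide by the duration model's mean to obtain its per-read ``scale``.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ModelError("need at least two samples to estimate dwell")
    dx = np.diff(x)
    spread = 1.4826 * np.median(np.abs(dx - np.median(dx)))
    count = int((np.abs(dx) > change_threshold * spread).sum())
    return float(np.clip(x.size / max(count, 1), *clip))


# ---------------------------------------------------------------------------
# observations


@runtime_checkable
class ObservationScorer(Protocol):
    """Maps a signal of length N to an N x |K| table of positive scores.

    Implementations return the scores in the log domain; exponentials of the
    returned values must be finite and strictly positive for finite input.
    """

    def log_scores(self, signal: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class GaussianObservation:
    """Per-k-mer Gaussian emission table (the classical pore model)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        if self.mu.shape != self.sigma.shape:
            raise ModelError("mu and sigma must have the same shape")
        if (self.sigma <= 0).any():
            raise ModelError("all sigma must be positive")

    def log_scores(self, signal: np.ndarray) -> np.ndarray:
        return gaussian_scores(signal, self)


def gaussian_scores(signal, obs: GaussianObservation) -> np.ndarray:
    """log phi[n, K] = log Normal(x_n; mu_K, sigma_K), shape N x |K|."""
    x = np.asarray(signal, dtype=float)
    if not np.isfinite(x).all():
        raise ModelError("signal contains non-finite samples")
    return stats.norm.logpdf(x[:, None], loc=obs.mu[None, :], scale=obs.sigma[None, :])


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadRecord:
    """One raw read: normalized current samples plus optional ground truth."""

    signal: np.ndarray
    read_id: str = ""
    truth_kmers: np.ndarray | None = None
    truth_durations: np.ndarray | None = None
    duration_scale: float | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.truth_kmers is not None:
            self.truth_kmers = np.asarray(self.truth_kmers, dtype=np.int64)
        if self.truth_durations is not None:
            self.truth_durations = np.asarray(self.truth_durations, dtype=np.int64)
            if (self.truth_durations < 1).any():
                raise ModelError("truth durations must all be >= 1")
            if self.truth_kmers is not None and self.truth_durations.sum() != len(
                self.signal
            ):
                raise ModelError("signal length must equal the sum of truth durations")
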