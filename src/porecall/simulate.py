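"""Synthetic nanopore squiggle generator with ground truth.

Reads are drawn exactly from the generative model the inference lattice
assumes: a geometrically distributed (or fixed) number of k-mers M, a
single-base-shift Markov chain over k-mers, i.i.d. dwell times from the
explicit duration table with its geometric tail, and one Gaussian current
sample per time step conditioned on the occupying k-mer.  An optional
per-read multiplicative dwell drift emulates the slowdown of translocation
across a sequencing run as ATP is depleted.

Every read carries its true k-mer and dwell sequences, so decoding and
training can be evaluated without real sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import KmerAlphabet
from .models import (
    DurationModel,
    GaussianObservation,
    ModelError,
    ReadRecord,
    TransitionModel,
)

__all__ = [
    "SimulatorConfig",
    "synthetic_pore_model",
    "random_reference",
    "simulate_read",
    "simulate_run",
    "empirical_transition_check",
]


@dataclass(frozen=True)
class SimulatorConfig:
    """Study conditions for a synthetic run.

    ``length_alpha`` is the continuation probability of the geometric
    read-length prior zeta(M) = (1-alpha) * alpha**M; draws are truncated at
    M >= 1, so the realized mean is 1/(1-alpha) (≈ alpha/(1-alpha) for alpha
    near 1, the regime of real reads).  ``fixed_m`` overrides it with a
    constant k-mer count.  ``noise_scale`` multiplies all emission sigmas;
    ``depletion_rate`` grows the mean dwell of read i by (1+rate)**i.
    """

    alphabet: KmerAlphabet
    transitions: TransitionModel
    durations: DurationModel
    observation: GaussianObservation
    length_alpha: float = 0.99
    fixed_m: int | None = None
    noise_scale: float = 1.0
    depletion_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.length_alpha < 1.0:
            raise ModelError("length_alpha must be in [0, 1)")
        if self.fixed_m is not None and self.fixed_m < 1:
            raise ModelError("fixed_m must be >= 1")
        if self.noise_scale < 0 or self.depletion_rate < 0:
            raise ModelError("noise_scale and depletion_rate must be >= 0")


def synthetic_pore_model(
    alphabet: KmerAlphabet, sigma: float = 0.08, spread: float = 2.0, seed: int = 7
) -> GaussianObservation:
    """A reproducible per-k-mer Gaussian table in normalized signal units.

    Means are drawn once (fixed seed) uniformly on [-spread, spread] — the
    typical dynamic range of a median-normalized squiggle — with a common
    ``sigma``.  This is a synthetic stand-in for a measured pore model.
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(-spread, spread, size=alphabet.size)
    return GaussianObservation(mu=mu, sigma=np.full(alphabet.size, float(sigma)))


def random_reference(
    length: int, p_repeat: float = 0.25, bases: str = "ACGT", seed: int = 0
) -> str:
    """A random reference sequence with tunable homopolymer content.

    Each base repeats the previous one with probability ``p_repeat`` and is
    drawn uniformly otherwise, giving geometric homopolymer run lengths with
    mean 1/(1 - p_repeat - (1-p_repeat)/|bases|).  ``p_repeat = 1/|bases|``
    reduces to i.i.d. bases; larger values enrich the runs that make
    basecalling dwell-limited — the regime the duration model targets.
    """
    rng = np.random.default_rng(seed)
    out = [bases[rng.integers(len(bases))]]
    for _ in range(length - 1):
        if rng.random() < p_repeat:
            out.append(out[-1])
        else:
            out.append(bases[rng.integers(len(bases))])
    return "".join(out)


def sample_durations(dm: DurationModel, size: int, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. dwell draws: explicit categorical head + geometric tail."""
    entry = dm.entry_probs()
    d = rng.choice(np.arange(1, dm.dbar + 1), size=size, p=entry)
    if dm.gamma > 0:
        at_tail = d == dm.dbar
        # extra tail samples: P(extra = m) = (1-gamma) * gamma**m, m >= 0
        d[at_tail] += rng.geometric(1.0 - dm.gamma, size=int(at_tail.sum())) - 1
    return d


def simulate_read(
    cfg: SimulatorConfig, seed: int | np.random.Generator, read_id: str = "read_0",
    duration_scale: float = 1.0,
) -> ReadRecord:
    """Draw one read: (M, K, D) from the prior, then the signal."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cfg.fixed_m is not None:
        m = cfg.fixed_m
    else:
        # shifted geometric, truncated at M >= 1
        m = int(rng.geometric(1.0 - cfg.length_alpha))
    kmers = np.empty(m, dtype=np.int64)
    kmers[0] = rng.choice(cfg.alphabet.size, p=cfg.transitions.xi0)
    xi = cfg.transitions.xi
    for i in range(1, m):
        kmers[i] = rng.choice(cfg.alphabet.size, p=xi[kmers[i - 1]])
    dm = cfg.durations if duration_scale == 1.0 else cfg.durations.rescaled(duration_scale)
    durations = sample_durations(dm, m, rng)
    mu = np.repeat(cfg.observation.mu[kmers], durations)
    sigma = np.repeat(cfg.observation.sigma[kmers], durations) * cfg.noise_scale
    signal = mu + (rng.standard_normal(mu.size) * sigma if cfg.noise_scale > 0 else 0.0)
    return ReadRecord(
        signal=signal,
        read_id=read_id,
        truth_kmers=kmers,
        truth_durations=durations,
        duration_scale=duration_scale,
    )


def simulate_run(
    cfg: SimulatorConfig, n_reads: int, seed: int, outdir=None
) -> list[ReadRecord]:
    """Draw a batch; read i gets dwell scale (1 + depletion_rate)**i.

    Read ids carry increasing ordinals so the across-run drift can be
    recovered from the output alone.  With ``outdir`` set, the batch is also
    written to disk: one single-column signal file per read under
    ``signals/``, the truth sequences as FASTA, and the truth alignment as a
    (read_id, kmer_index, duration) TSV.
    """
    if n_reads < 1:
        raise ModelError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        scale = (1.0 + cfg.depletion_rate) ** i
        reads.append(simulate_read(cfg, rng, read_id=f"read_{i:06d}", duration_scale=scale))
    if outdir is not None:
        write_run(outdir, reads, cfg.alphabet)
    return reads


def write_run(outdir, reads: list[ReadRecord], alphabet: KmerAlphabet) -> None:
    """Write signals, truth FASTA and truth alignment TSV for a batch."""
    from pathlib import Path

    from . import io as pio
    from .alphabet import sequence_from_kmers

    outdir = Path(outdir)
    (outdir / "signals").mkdir(parents=True, exist_ok=True)
    for read in reads:
        pio.write_signal(outdir / "signals" / f"{read.read_id}.txt", read.signal)
    pio.write_fasta(
        outdir / "truth.fasta",
        {r.read_id: sequence_from_kmers(r.truth_kmers, alphabet) for r in reads},
    )
    pio.write_truth_table(outdir / "truth_alignment.tsv", reads)


def empirical_transition_check(reads: list[ReadRecord], alphabet: KmerAlphabet) -> np.ndarray:
    """Bigram frequencies of consecutive truth k-mers (rows sum to 1).

    Simulator self-test: for a uniform-shift chain each of the ``|bases|``
    successors should appear with frequency 1/|bases|.  Rows for k-mers
    never visited as a transition source are left at zero.
    """
    counts = np.zeros((alphabet.size, alphabet.size))
    for read in reads:
        if read.truth_kmers is None:
            raise ModelError(f"read {read.read_id} has no ground truth")
        kk = read.truth_kmers
        if kk.size >= 2:
            np.add.at(counts, (kk[:-1], kk[1:]), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, counts / totals, 0.0)
    return freq
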