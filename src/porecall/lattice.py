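"""The explicit-duration HMM lattice and exact inference on it.

State space
-----------
Besides a start state A and an end state B, the model has ``|K| * Dbar``
intermediate states (K, d): k-mer K with d samples left in its dwell.  A
random walk from A to B draws a k-mer/dwell sequence:

1. A enters (K1, d) with probability ``alpha * xi0(K1) * eta(d)`` for
   d < Dbar, enters (K1, Dbar) with ``alpha * xi0(K1) * eta(Dbar)/(1-gamma)``
   (the Dbar state absorbs the whole geometric tail), and moves straight to
   B with probability ``1 - alpha``.
2. (K, d) counts down deterministically to (K, d-1) for 2 <= d < Dbar.
3. (K, Dbar) self-transitions with probability ``gamma`` (realizing dwell
   times beyond Dbar) and moves to (K, Dbar-1) with ``1 - gamma``.
4. (K, 1) enters a new k-mer (K', d') with probability
   ``alpha * xi(K'|K) * eta(d')`` (Dbar entry scaled by 1/(1-gamma) as
   above) or terminates in B with probability ``1 - alpha``.

Each intermediate state emits one sample with score phi[n, K]; observations
are shared across d.  Reads of length N correspond to A->B paths with N
intermediate steps; being in some (K, 1) at sample N marks the completion
of the final k-mer.  With ``alpha = 1`` (the convention used for inference,
where the geometric read-length prior degenerates) the B transitions carry
no mass and termination is imposed by conditioning on (K, 1) occupancy at
time N.

For ``Dbar == 1`` the dwell law is purely geometric: (K, 1) self-loops with
probability gamma and every exit out of the k-mer (including termination)
carries the remaining factor ``1 - gamma``.

All recursions run in the natural-log domain with log-sum-exp; the
*clamped* lattice restricts the k-mer layer to one target sequence K (its
forward pass gives p(K, X)), the *free-running* lattice sums over all
sequences (giving p(X)).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from . import _dp
from .alphabet import KmerAlphabet
from .models import DurationModel, TransitionModel

__all__ = [
    "StateSpace",
    "TrellisResult",
    "OccupancyMatrix",
    "ViterbiPath",
    "BruteForceResult",
    "build_state_space",
    "forward_free",
    "forward_clamped",
    "occupancy",
    "viterbi_joint",
    "forced_alignment",
    "sequence_posterior",
    "enumerate_bruteforce",
]


class LatticeError(ValueError):
    pass


class EnumerationLimitError(RuntimeError):
    """Brute-force enumeration would exceed the configured path budget."""


def _log(x) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


@dataclass(frozen=True)
class _EdgeArrays:
    """Padded predecessor/successor representation of one lattice."""

    logpi: np.ndarray  # (S,)
    logterm: np.ndarray  # (S,)
    emit: np.ndarray  # (S,) k-mer index per state
    pred_idx: np.ndarray  # (S, P) int64
    pred_logw: np.ndarray  # (S, P)
    pred_entry: np.ndarray  # (S, P) bool: edge starts a new k-mer
    succ_idx: np.ndarray
    succ_logw: np.ndarray

    @property
    def n_states(self) -> int:
        return self.logpi.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.isfinite(self.pred_logw).sum())


def _pack_edges(n_states, edges, logpi, logterm, emit) -> _EdgeArrays:
    """edges: list of (src, dst, logw, is_entry); slots sorted by src index."""
    by_dst: list[list[tuple[int, float, bool]]] = [[] for _ in range(n_states)]
    by_src: list[list[tuple[int, float]]] = [[] for _ in range(n_states)]
    for src, dst, logw, entry in edges:
        by_dst[dst].append((src, logw, entry))
        by_src[src].append((dst, logw))
    # deterministic slot order: lowest predecessor state first, countdown
    # edges before entry edges from the same state (Viterbi tie-break)
    for lst in by_dst:
        lst.sort(key=lambda t: (t[0], t[2]))
    pmax = max(1, max(len(l) for l in by_dst))
    smax = max(1, max(len(l) for l in by_src))
    pred_idx = np.zeros((n_states, pmax), dtype=np.int64)
    pred_logw = np.full((n_states, pmax), -np.inf)
    pred_entry = np.zeros((n_states, pmax), dtype=bool)
    succ_idx = np.zeros((n_states, smax), dtype=np.int64)
    succ_logw = np.full((n_states, smax), -np.inf)
    for s, lst in enumerate(by_dst):
        for p, (src, logw, entry) in enumerate(lst):
            pred_idx[s, p] = src
            pred_logw[s, p] = logw
            pred_entry[s, p] = entry
    for s, lst in enumerate(by_src):
        for p, (dst, logw) in enumerate(lst):
            succ_idx[s, p] = dst
            succ_logw[s, p] = logw
    return _EdgeArrays(
        logpi=logpi,
        logterm=logterm,
        emit=emit.astype(np.int64),
        pred_idx=pred_idx,
        pred_logw=pred_logw,
        pred_entry=pred_entry,
        succ_idx=succ_idx,
        succ_logw=succ_logw,
    )


@dataclass(frozen=True)
class StateSpace:
    """Free-running lattice over all k-mer sequences.

    Intermediate state (K, d) has flat index ``K * Dbar + (d - 1)``.
    """

    alphabet: KmerAlphabet
    transitions: TransitionModel
    durations: DurationModel
    alpha: float
    arrays: _EdgeArrays

    @property
    def dbar(self) -> int:
        return self.durations.dbar

    @property
    def n_states(self) -> int:
        return self.arrays.n_states

    @property
    def exit_factor(self) -> float:
        """Multiplier applied when leaving a k-mer from (K, 1).

        For Dbar == 1 the single duration state carries the geometric tail
        self-loop, so exits (including termination) carry 1 - gamma;
        otherwise the (Dbar -> Dbar-1) edge already paid that factor.
        """
        return 1.0 - self.durations.gamma if self.dbar == 1 else 1.0

    def state_index(self, kmer: int, d: int) -> int:
        return kmer * self.dbar + (d - 1)

    def outgoing_mass(self) -> dict[str, float]:
        """Total outgoing probability per state class, including the A->...
        and ...->B transitions (which are not lattice edges).  Used to check
        the model is a proper Markov chain for any alpha."""
        entry = self.durations.entry_probs()
        out = {"A": self.alpha * float(self.transitions.xi0.sum()) + (1.0 - self.alpha)}
        ex = self.exit_factor
        for kmer in range(self.alphabet.size):
            for d in range(1, self.dbar + 1):
                s = self.state_index(kmer, d)
                if d == 1:
                    row = float(self.transitions.xi[kmer].sum())
                    mass = ex * (
                        self.alpha * row * float(entry.sum()) + (1.0 - self.alpha)
                    )
                    if self.dbar == 1:
                        mass += self.durations.gamma
                    out[f"({kmer},{d})"] = mass
                elif d == self.dbar:
                    out[f"({kmer},{d})"] = self.durations.gamma + (1.0 - self.durations.gamma)
                else:
                    out[f"({kmer},{d})"] = 1.0
        return out

    def summary(self) -> str:
        return (
            f"StateSpace: |K|={self.alphabet.size} (k={self.alphabet.k}), "
            f"Dbar={self.dbar}, states={self.n_states}, "
            f"edges={self.arrays.n_edges}, alpha={self.alpha}"
        )


def build_state_space(
    alphabet: KmerAlphabet,
    transitions: TransitionModel,
    durations: DurationModel,
    alpha: float = 1.0,
) -> StateSpace:
    """Assemble the free-running lattice from the four transition rules."""
    if not 0.0 <= alpha <= 1.0:
        raise LatticeError(f"alpha must be in [0, 1], got {alpha}")
    nk = alphabet.size
    dbar = durations.dbar
    gamma = durations.gamma
    entry = durations.entry_probs()
    log_entry = _log(entry)
    log_alpha = _log(alpha) if alpha > 0 else -np.inf
    exit1 = 1.0 - gamma if dbar == 1 else 1.0
    log_exit1 = _log(exit1)

    S = nk * dbar
    edges: list[tuple[int, int, float, bool]] = []
    succ_tab, succ_logxi = transitions.successor_table()
    for kmer in range(nk):
        base = kmer * dbar
        if dbar >= 2:
            # rule 2: deterministic countdown
            for d in range(2, dbar):
                edges.append((base + d - 1, base + d - 2, 0.0, False))
            # rule 3: tail self-loop and release
            if gamma > 0:
                edges.append((base + dbar - 1, base + dbar - 1, np.log(gamma), False))
            edges.append((base + dbar - 1, base + dbar - 2, np.log1p(-gamma), False))
        elif gamma > 0:
            edges.append((base, base, np.log(gamma), False))
        # rule 4: k-mer change from (K, 1)
        for nxt, logxi in zip(succ_tab[kmer], succ_logxi[kmer]):
            if logxi == -np.inf:
                continue
            for d in range(1, dbar + 1):
                w = log_alpha + log_exit1 + logxi + log_entry[d - 1]
                edges.append((base, int(nxt) * dbar + d - 1, w, True))

    logpi = np.full(S, -np.inf)
    for kmer in range(nk):
        for d in range(1, dbar + 1):
            logpi[kmer * dbar + d - 1] = (
                log_alpha + _log(transitions.xi0[kmer]) + log_entry[d - 1]
            )
    logterm = np.full(S, -np.inf)
    log_term_b = _log(1.0 - alpha) if alpha < 1.0 else 0.0
    logterm[0::dbar] = log_exit1 + log_term_b

    emit = np.repeat(np.arange(nk, dtype=np.int64), dbar)
    arrays = _pack_edges(S, edges, logpi, logterm, emit)
    return StateSpace(alphabet, transitions, durations, alpha, arrays)


def _clamped_arrays(ss: StateSpace, kmers: np.ndarray) -> _EdgeArrays:
    """Lattice of size (M * Dbar) restricted to one k-mer sequence."""
    kmers = np.asarray(kmers, dtype=np.int64)
    if kmers.ndim != 1 or kmers.size == 0:
        raise LatticeError("clamped lattice needs a non-empty k-mer sequence")
    if (kmers < 0).any() or (kmers >= ss.alphabet.size).any():
        raise LatticeError("k-mer index out of range for the alphabet")
    M = kmers.size
    dbar = ss.dbar
    gamma = ss.durations.gamma
    log_entry = _log(ss.durations.entry_probs())
    log_alpha = _log(ss.alpha) if ss.alpha > 0 else -np.inf
    log_exit1 = _log(ss.exit_factor)

    S = M * dbar
    edges: list[tuple[int, int, float, bool]] = []
    for m in range(M):
        base = m * dbar
        if dbar >= 2:
            for d in range(2, dbar):
                edges.append((base + d - 1, base + d - 2, 0.0, False))
            if gamma > 0:
                edges.append((base + dbar - 1, base + dbar - 1, np.log(gamma), False))
            edges.append((base + dbar - 1, base + dbar - 2, np.log1p(-gamma), False))
        elif gamma > 0:
            edges.append((base, base, np.log(gamma), False))
        if m + 1 < M:
            logxi = _log(ss.transitions.xi[kmers[m], kmers[m + 1]])
            for d in range(1, dbar + 1):
                w = log_alpha + log_exit1 + logxi + log_entry[d - 1]
                edges.append((base, (m + 1) * dbar + d - 1, w, True))

    logpi = np.full(S, -np.inf)
    logpi[:dbar] = log_alpha + _log(ss.transitions.xi0[kmers[0]]) + log_entry
    logterm = np.full(S, -np.inf)
    log_term_b = _log(1.0 - ss.alpha) if ss.alpha < 1.0 else 0.0
    logterm[(M - 1) * dbar] = log_exit1 + log_term_b
    emit = np.repeat(kmers, dbar)
    return _pack_edges(S, edges, logpi, logterm, emit)


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class TrellisResult:
    mode: str  # "free_running" | "clamped"
    log_forward: np.ndarray  # (N, S)
    log_likelihood: float  # log p(X) or log p(K, X)


@dataclass(frozen=True)
class OccupancyMatrix:
    """gamma[n, K]: posterior probability that sample n was emitted by K."""

    gamma: np.ndarray  # (N, |K|)
    mode: str


@dataclass(frozen=True)
class ViterbiPath:
    kmers: np.ndarray
    durations: np.ndarray
    log_joint: float


@dataclass(frozen=True)
class BruteForceResult:
    log_px: float
    log_pkx: dict[tuple[int, ...], float]  # per k-mer sequence
    argmax_kmers: tuple[int, ...]
    argmax_durations: tuple[int, ...]
    argmax_log_joint: float
    n_paths: int


# ---------------------------------------------------------------------------
# exact inference


def _check_scores(log_phi: np.ndarray, nk: int) -> np.ndarray:
    log_phi = np.asarray(log_phi, dtype=float)
    if log_phi.ndim != 2 or log_phi.shape[1] != nk:
        raise LatticeError(f"score matrix must be N x {nk}, got {log_phi.shape}")
    if log_phi.shape[0] == 0:
        raise LatticeError("empty score matrix (N = 0)")
    if not np.isfinite(log_phi).all():
        raise LatticeError("scores must be strictly positive and finite")
    return log_phi


def forward_free(log_phi: np.ndarray, ss: StateSpace) -> TrellisResult:
    """log p(X): forward pass on the free-running lattice.

    ``log_phi`` is the N x |K| score matrix in the log domain.
    """
    log_phi = _check_scores(log_phi, ss.alphabet.size)
    a = ss.arrays
    F = _dp.forward_pass(a.logpi, a.emit, a.pred_idx, a.pred_logw, log_phi)
    ll = float(logsumexp(F[-1] + a.logterm))
    return TrellisResult("free_running", F, ll)


def forward_clamped(log_phi: np.ndarray, kmers, ss: StateSpace) -> TrellisResult:
    """log p(K, X): forward pass on the lattice clamped to sequence K.

    Returns -inf log-likelihood when no duration assignment fits (e.g. when
    the sequence is longer than the read, M > N).
    """
    log_phi = _check_scores(log_phi, ss.alphabet.size)
    a = _clamped_arrays(ss, kmers)
    F = _dp.forward_pass(a.logpi, a.emit, a.pred_idx, a.pred_logw, log_phi)
    ll = float(logsumexp(F[-1] + a.logterm))
    return TrellisResult("clamped", F, ll)


def _posterior(log_phi: np.ndarray, a: _EdgeArrays, nk: int) -> tuple[np.ndarray, float]:
    F = _dp.forward_pass(a.logpi, a.emit, a.pred_idx, a.pred_logw, log_phi)
    B = _dp.backward_pass(a.logterm, a.emit, a.succ_idx, a.succ_logw, log_phi)
    ll = float(logsumexp(F[-1] + a.logterm))
    if not np.isfinite(ll):
        raise LatticeError("zero-likelihood read: no feasible path")
    post = np.exp(F + B - ll)  # (N, S)
    gamma = np.zeros((log_phi.shape[0], nk))
    np.add.at(gamma.T, a.emit, post.T)
    return gamma, ll


def occupancy(log_phi: np.ndarray, ss: StateSpace, kmers=None) -> OccupancyMatrix:
    """Per-sample k-mer visit probabilities p(K_n = K | X) (free-running)
    or p(K_n = K | X, K) (clamped, mapped back to k-mer identities)."""
    log_phi = _check_scores(log_phi, ss.alphabet.size)
    if kmers is None:
        gamma, _ = _posterior(log_phi, ss.arrays, ss.alphabet.size)
        return OccupancyMatrix(gamma, "free_running")
    gamma, _ = _posterior(log_phi, _clamped_arrays(ss, kmers), ss.alphabet.size)
    return OccupancyMatrix(gamma, "clamped")


def _backtrack(a: _EdgeArrays, F: np.ndarray, bp: np.ndarray, dbar: int):
    """Best terminal state, its state path, and per-step entry flags."""
    N = F.shape[0]
    scores = F[-1] + a.logterm
    s = int(np.argmax(scores))
    if not np.isfinite(scores[s]):
        raise LatticeError("zero-likelihood read: no feasible path")
    log_joint = float(scores[s])
    states = np.empty(N, dtype=np.int64)
    entry = np.zeros(N, dtype=bool)  # entry[n]: new k-mer starts at sample n
    states[-1] = s
    for n in range(N - 1, 0, -1):
        p = bp[n, s]
        entry[n] = a.pred_entry[s, p]
        s = int(a.pred_idx[s, p])
        states[n - 1] = s
    entry[0] = True
    return log_joint, states, entry


def viterbi_joint(log_phi: np.ndarray, ss: StateSpace) -> ViterbiPath:
    """Jointly most likely (K, D): max-product on the free-running lattice.

    Ties are broken toward the lowest state index.  Durations report true
    dwell lengths (self-loop visits at Dbar are counted, not capped).
    """
    log_phi = _check_scores(log_phi, ss.alphabet.size)
    a = ss.arrays
    F, bp = _dp.viterbi_pass(a.logpi, a.emit, a.pred_idx, a.pred_logw, log_phi)
    log_joint, states, entry = _backtrack(a, F, bp, ss.dbar)
    starts = np.flatnonzero(entry)
    kmers = a.emit[states[starts]]
    durations = np.diff(np.append(starts, len(states)))
    return ViterbiPath(kmers, durations, log_joint)


def forced_alignment(log_phi: np.ndarray, kmers, ss: StateSpace):
    """Clamped Viterbi: most likely sample-to-k-mer alignment.

    Returns ``(labels, durations)`` where ``labels[n]`` is the k-mer index
    emitting sample n (M contiguous runs, in the order of K) and
    ``durations`` are the run lengths (summing to N).
    """
    log_phi = _check_scores(log_phi, ss.alphabet.size)
    kmers = np.asarray(kmers, dtype=np.int64)
    if kmers.size > log_phi.shape[0]:
        raise LatticeError(
            f"infeasible alignment: M={kmers.size} k-mers need more than "
            f"N={log_phi.shape[0]} samples"
        )
    a = _clamped_arrays(ss, kmers)
    F, bp = _dp.viterbi_pass(a.logpi, a.emit, a.pred_idx, a.pred_logw, log_phi)
    _, states, entry = _backtrack(a, F, bp, ss.dbar)
    starts = np.flatnonzero(entry)
    durations = np.diff(np.append(starts, len(states)))
    labels = np.repeat(kmers, durations)
    return labels, durations


def sequence_posterior(log_phi: np.ndarray, kmers, ss: StateSpace) -> float:
    """p(K | X) = p(K, X) / p(X) via the two forward passes."""
    free = forward_free(log_phi, ss)
    if not np.isfinite(free.log_likelihood):
        raise LatticeError("p(X) = 0: cannot form a posterior")
    clamped = forward_clamped(log_phi, kmers, ss)
    return float(np.exp(clamped.log_likelihood - free.log_likelihood))


# ---------------------------------------------------------------------------
# brute-force oracle


def enumerate_bruteforce(
    log_phi: np.ndarray, ss: StateSpace, limit: int = 500_000
) -> BruteForceResult:
    """Exhaustive sum/max over every (K, D) pair with sum(D) = N.

    Weights each path directly by the generative factorization — initial and
    transition probabilities, the dwell pmf with its geometric tail expanded
    analytically up to N, the per-sample scores, and the read-length prior
    factors alpha**M (and 1-alpha when alpha < 1).  Independent of the
    lattice recursions; intended as a test oracle on tiny instances.
    Refuses instances whose path count would exceed ``limit``.
    """
    log_phi = _check_scores(log_phi, ss.alphabet.size)
    N = log_phi.shape[0]
    tm = ss.transitions
    log_xi0 = tm.log_xi0()
    log_xi = tm.log_xi()
    log_dur = _log(ss.durations.pmf(np.arange(1, N + 1)))
    log_alpha = _log(ss.alpha) if ss.alpha > 0 else -np.inf
    log_term = _log(1.0 - ss.alpha) if ss.alpha < 1.0 else 0.0

    # cumulative per-k-mer score sums: segment [i, j) costs cum[j,K]-cum[i,K]
    cum = np.vstack([np.zeros(ss.alphabet.size), np.cumsum(log_phi, axis=0)])

    n_paths = 0
    log_px_parts: list[float] = []
    table: dict[tuple[int, ...], list[float]] = {}
    best = (-np.inf, (), ())

    nk = ss.alphabet.size
    support = [np.flatnonzero(tm.xi[kmer]) for kmer in range(nk)]
    starts = np.flatnonzero(tm.xi0)

    def sequences(M: int):
        stack = [(int(k0), [int(k0)], float(log_xi0[k0])) for k0 in starts]
        while stack:
            last, seq, w = stack.pop()
            if len(seq) == M:
                yield seq, w
                continue
            for nxt in support[last]:
                stack.append((int(nxt), seq + [int(nxt)], w + float(log_xi[last, nxt])))

    for M in range(1, N + 1):
        cuts = list(combinations(range(1, N), M - 1))
        for seq, w_seq in sequences(M):
            w_seq = w_seq + M * log_alpha + log_term
            key = tuple(seq)
            parts = table.setdefault(key, [])
            for cut in cuts:
                n_paths += 1
                if n_paths > limit:
                    raise EnumerationLimitError(
                        f"more than {limit} paths; refuse to enumerate"
                    )
                bounds = (0,) + cut + (N,)
                w = w_seq
                for m in range(M):
                    i, j = bounds[m], bounds[m + 1]
                    w += log_dur[j - i - 1] + (cum[j, seq[m]] - cum[i, seq[m]])
                parts.append(w)
                if w > best[0]:
                    durs = tuple(
                        bounds[m + 1] - bounds[m] for m in range(M)
                    )
                    best = (w, key, durs)
                log_px_parts.append(w)

    log_pkx = {
        key: float(logsumexp(parts)) for key, parts in table.items() if parts
    }
    return BruteForceResult(
        log_px=float(logsumexp(log_px_parts)),
        log_pkx=log_pkx,
        argmax_kmers=best[1],
        argmax_durations=best[2],
        argmax_log_joint=best[0],
        n_paths=n_paths,
    )
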