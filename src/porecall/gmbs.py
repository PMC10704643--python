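"""Greedy marginalized beam search (GMBS) decoding.

Approximates ``argmax_K p(K | X)`` by maintaining a fixed-size list of B
k-mer prefixes ("beams") with high posterior mass.  Unlike Viterbi — which
commits to a single jointly optimal (K, D) path — each beam carries a
duration-resolved mass vector ``p(K_m, current dwell state d | X_1..n)`` and
marginalizes over dwell time, which is what makes the decoder competitive in
homopolymer regions where only dwell statistics distinguish run lengths.

Per sample n the algorithm (i) advances every beam's duration mass by the
within-k-mer dynamics (deterministic countdown; self-loop with factor gamma
at the maximum explicit duration) weighted by the beam k-mer's score,
(ii) spawns, from the mass at d = 1, one extension per successor k-mer with
entry mass split over entry durations, (iii) merges identical prefixes by
summing duration masses, and (iv) prunes to the top B prefixes by total
mass.  Prefixes live in a backtrackable tree (at most N*B + 1 nodes); the
decoded sequence is read from the best completable leaf back to the root.
Per-step renormalization (tracked as an accumulated log constant) keeps the
linear-domain masses away from underflow without changing the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import StateSpace

__all__ = ["GMBSConfig", "Beam", "BeamTree", "gmbs_decode", "prune_beams", "backtrack_tree"]


class DecodeError(RuntimeError):
    """All beams lost their probability mass; the decode cannot finish."""


@dataclass(frozen=True)
class GMBSConfig:
    """Beam-search settings: beam count B and per-step renormalization."""

    beams: int = 512
    normalize: bool = True

    def __post_init__(self):
        if self.beams < 1:
            raise ValueError("need at least one beam")


@dataclass
class BeamTree:
    """Prefix tree: node i stores its parent and the k-mer appended there.

    The root (node 0) is the empty prefix.  Common ancestry encodes common
    initial substrings, so a full decode allocates at most N*B + 1 nodes.
    """

    parent: list[int] = field(default_factory=lambda: [-1])
    label: list[int] = field(default_factory=lambda: [-1])

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def add(self, parent: int, label: int) -> int:
        self.parent.append(parent)
        self.label.append(label)
        return len(self.parent) - 1


@dataclass
class Beam:
    """One k-mer prefix with duration-resolved posterior mass."""

    node: int  # reference into the BeamTree
    kmer: int  # last k-mer of the prefix (-1 for the root)
    duration_mass: np.ndarray  # (Dbar,) p(prefix, dwell state d | X_1..n)

    @property
    def total_mass(self) -> float:
        return float(self.duration_mass.sum())


def backtrack_tree(tree: BeamTree, leaf: int) -> np.ndarray:
    """k-mer labels on the root-to-leaf path, in order."""
    if not 0 <= leaf < tree.n_nodes:
        raise IndexError(f"node {leaf} not in tree of size {tree.n_nodes}")
    out = []
    node = leaf
    while node != 0:
        out.append(tree.label[node])
        node = tree.parent[node]
    return np.array(out[::-1], dtype=np.int64)


def prune_beams(beams: list[Beam], b: int) -> list[Beam]:
    """Top-``b`` beams by total mass, stable under ties (creation order)."""
    if len(beams) <= b:
        return list(beams)
    totals = np.array([bm.total_mass for bm in beams])
    order = np.argsort(-totals, kind="stable")[:b]
    return [beams[i] for i in sorted(order, key=lambda i: totals[i], reverse=True)]


def _decode_arrays(ss: StateSpace):
    succ, succ_logxi = ss.transitions.successor_table()
    with np.errstate(over="ignore"):
        succ_xi = np.exp(succ_logxi)
    return succ, succ_xi, ss.durations.entry_probs()


def gmbs_decode(
    log_phi: np.ndarray,
    ss: StateSpace,
    cfg: GMBSConfig = GMBSConfig(),
    return_tree: bool = False,
):
    """Decode a score matrix into the highest-posterior-mass k-mer sequence.

    Returns ``(kmers, log_mass)`` where ``log_mass`` estimates
    log p(K_hat, X) (the best beam's terminal duration-marginalized mass,
    with the accumulated renormalization constant restored).  With
    ``return_tree=True`` the beam tree is appended to the tuple.
    """
    log_phi = np.asarray(log_phi, dtype=float)
    N, nk = log_phi.shape
    if N < 1:
        raise DecodeError("cannot decode an empty read")
    dbar = ss.dbar
    gamma = ss.durations.gamma
    exit1 = ss.exit_factor * ss.alpha
    succ, succ_xi, entry = _decode_arrays(ss)
    n_succ = succ.shape[1]
    tree = BeamTree()
    # (parent node, appended k-mer) -> child node, so the same prefix reached
    # again (entered at a later sample) merges into one beam
    child_index: dict[tuple[int, int], int] = {}
    log_norm = 0.0

    # initialization: one beam per k-mer with positive prior mass
    shift = log_phi[0].max()
    phi0 = np.exp(log_phi[0] - shift)
    log_norm += shift
    mass = ss.transitions.xi0[:, None] * entry[None, :] * phi0[:, None]  # (nk, Dbar)
    order = np.argsort(-mass.sum(axis=1), kind="stable")[: cfg.beams]
    order = order[mass[order].sum(axis=1) > 0]
    kmers = order.astype(np.int64)
    masses = mass[order]
    nodes = np.empty(kmers.size, dtype=np.int64)
    for i, kk in enumerate(kmers):
        nodes[i] = tree.add(0, int(kk))
        child_index[(0, int(kk))] = int(nodes[i])

    for n in range(1, N):
        B = len(kmers)
        shift = log_phi[n].max()
        phi = np.exp(log_phi[n] - shift)
        log_norm += shift

        # within-k-mer advance
        adv = np.zeros_like(masses)
        if dbar >= 2:
            adv[:, : dbar - 2] = masses[:, 1 : dbar - 1]
            adv[:, dbar - 2] += masses[:, dbar - 1] * (1.0 - gamma)
            adv[:, dbar - 1] += masses[:, dbar - 1] * gamma
        else:
            adv[:, 0] = masses[:, 0] * gamma
        adv *= phi[kmers][:, None]

        # extensions from the completed-k-mer mass (d = 1)
        exit_mass = masses[:, 0] * exit1  # (B,)
        ext_kmers = succ[kmers]  # (B, n_succ)
        ext_mass = (
            exit_mass[:, None, None]
            * succ_xi[kmers][:, :, None]
            * entry[None, None, :]
            * phi[ext_kmers][:, :, None]
        )  # (B, n_succ, Dbar)

        # merge candidates by prefix: advanced beams keep their node; an
        # extension either lands on an already-materialized child node
        # (summing duration masses marginalizes over the entry sample) or
        # proposes a new node, materialized only if it survives pruning
        merged: dict[int, np.ndarray] = {}
        merged_kmer: dict[int, int] = {}
        for i in range(B):
            node = int(nodes[i])
            merged[node] = adv[i].copy()
            merged_kmer[node] = int(kmers[i])
        new_ext: list[tuple[int, int, np.ndarray]] = []  # (parent, kmer, mass)
        for i in range(B):
            if exit_mass[i] <= 0.0:
                continue
            parent = int(nodes[i])
            for s in range(n_succ):
                m = ext_mass[i, s]
                if succ_xi[kmers[i], s] <= 0.0:
                    continue
                child = child_index.get((parent, int(ext_kmers[i, s])))
                if child is not None:
                    if child in merged:
                        merged[child] += m
                    else:
                        merged[child] = m.copy()
                        merged_kmer[child] = int(ext_kmers[i, s])
                else:
                    new_ext.append((parent, int(ext_kmers[i, s]), m))

        cand_nodes = list(merged.keys())
        totals = np.array(
            [merged[c].sum() for c in cand_nodes] + [m.sum() for _, _, m in new_ext]
        )
        keep = np.argsort(-totals, kind="stable")[: cfg.beams]
        keep = keep[totals[keep] > 0.0]
        if keep.size == 0:
            raise DecodeError(f"all beams at zero mass at sample {n}")

        n_old = len(cand_nodes)
        new_masses = np.empty((keep.size, dbar))
        new_kmers = np.empty(keep.size, dtype=np.int64)
        new_nodes = np.empty(keep.size, dtype=np.int64)
        for i, c in enumerate(keep):
            if c < n_old:
                node = cand_nodes[c]
                new_masses[i] = merged[node]
                new_kmers[i] = merged_kmer[node]
                new_nodes[i] = node
            else:
                parent, kk, m = new_ext[int(c) - n_old]
                node = tree.add(parent, kk)
                child_index[(parent, kk)] = node
                new_masses[i] = m
                new_kmers[i] = kk
                new_nodes[i] = node
        masses, kmers, nodes = new_masses, new_kmers, new_nodes

        if cfg.normalize:
            z = masses.max()
            if z > 0:
                masses /= z
                log_norm += np.log(z)

    # termination: the final k-mer must complete on the last sample
    term = masses[:, 0] * ss.exit_factor
    if ss.alpha < 1.0:
        term = term * (1.0 - ss.alpha)
    best = int(np.argmax(term))
    if term[best] <= 0.0:
        raise DecodeError("no beam can terminate: zero completion mass")
    seq = backtrack_tree(tree, int(nodes[best]))
    log_mass = float(np.log(term[best]) + log_norm)
    if return_tree:
        return seq, log_mass, tree
    return seq, log_mass
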