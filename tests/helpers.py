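"""Shared test utilities: independent oracles and tiny model builders."""

from __future__ import annotations

import numpy as np

from porecall import DurationModel, build_kmer_alphabet, build_state_space
from porecall.models import uniform_shift_transitions


def edit_distance_dp(a: str, b: str) -> int:
    """Textbook quadratic Levenshtein DP (unit costs); alignment oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def duration_model_from_weights(weights, gamma: float) -> DurationModel:
    """Normalize arbitrary positive weights into a valid dwell table."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    eta = np.concatenate([w[:-1], [w[-1] * (1.0 - gamma)]])
    return DurationModel(eta=eta, gamma=gamma)


def tiny_state_space(k=1, n_bases=2, dbar=2, gamma=0.3, seed=0, alpha=1.0):
    """A small uniform-shift state space with a random dwell table."""
    rng = np.random.default_rng(seed)
    ab = build_kmer_alphabet(k, ("A", "C", "G", "T")[:n_bases])
    tm = uniform_shift_transitions(ab)
    dm = duration_model_from_weights(rng.random(dbar) + 0.1, gamma)
    return ab, tm, dm, build_state_space(ab, tm, dm, alpha=alpha)


def random_scores(n, size, seed=0):
    rng = np.random.default_rng(seed)
    return np.log(rng.random((n, size)) + 0.05)
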