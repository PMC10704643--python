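"""Numba kernels for log-domain lattice dynamic programming.

The lattice is given in a padded edge representation: ``pred_idx[s, p]`` and
``pred_logw[s, p]`` list the predecessors of state ``s`` (padding has weight
-inf), ``emit[s]`` maps a state to the k-mer row of the score matrix.  All
recursions use log-sum-exp (or max for Viterbi) with explicit -inf guards;
no scaling vectors are involved.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def forward_pass(logpi, emit, pred_idx, pred_logw, logphi):
    """Log forward table F[n, s]; F[0] from the initial distribution."""
    N = logphi.shape[0]
    S = logpi.shape[0]
    P = pred_idx.shape[1]
    F = np.full((N, S), NEG_INF)
    for s in range(S):
        if logpi[s] > NEG_INF:
            F[0, s] = logpi[s] + logphi[0, emit[s]]
    for n in range(1, N):
        for s in range(S):
            m = NEG_INF
            for p in range(P):
                w = pred_logw[s, p]
                if w == NEG_INF:
                    continue
                v = F[n - 1, pred_idx[s, p]] + w
                if v > m:
                    m = v
            if m == NEG_INF:
                continue
            acc = 0.0
            for p in range(P):
                w = pred_logw[s, p]
                if w == NEG_INF:
                    continue
                v = F[n - 1, pred_idx[s, p]] + w
                acc += np.exp(v - m)
            F[n, s] = m + np.log(acc) + logphi[n, emit[s]]
    return F


@njit(cache=True)
def backward_pass(logterm, emit, succ_idx, succ_logw, logphi):
    """Log backward table B[n, s]; B[N-1] is the termination weight."""
    N = logphi.shape[0]
    S = logterm.shape[0]
    P = succ_idx.shape[1]
    B = np.full((N, S), NEG_INF)
    for s in range(S):
        B[N - 1, s] = logterm[s]
    for n in range(N - 2, -1, -1):
        for s in range(S):
            m = NEG_INF
            for p in range(P):
                w = succ_logw[s, p]
                if w == NEG_INF:
                    continue
                t = succ_idx[s, p]
                v = w + logphi[n + 1, emit[t]] + B[n + 1, t]
                if v > m:
                    m = v
            if m == NEG_INF:
                continue
            acc = 0.0
            for p in range(P):
                w = succ_logw[s, p]
                if w == NEG_INF:
                    continue
                t = succ_idx[s, p]
                acc += np.exp(w + logphi[n + 1, emit[t]] + B[n + 1, t] - m)
            B[n, s] = m + np.log(acc)
    return B


@njit(cache=True)
def viterbi_pass(logpi, emit, pred_idx, pred_logw, logphi):
    """Max-product table and backpointers.

    ``bp[n, s]`` stores the predecessor *slot* p (not the state), so the
    caller can recover both the predecessor state and whether the chosen
    edge was a k-mer entry.  Ties go to the first slot, i.e. the lowest
    predecessor state index given the slot ordering used by the builder.
    """
    N = logphi.shape[0]
    S = logpi.shape[0]
    P = pred_idx.shape[1]
    F = np.full((N, S), NEG_INF)
    bp = np.full((N, S), -1, dtype=np.int32)
    for s in range(S):
        if logpi[s] > NEG_INF:
            F[0, s] = logpi[s] + logphi[0, emit[s]]
    for n in range(1, N):
        for s in range(S):
            best = NEG_INF
            arg = -1
            for p in range(P):
                w = pred_logw[s, p]
                if w == NEG_INF:
                    continue
                v = F[n - 1, pred_idx[s, p]] + w
                if v > best:
                    best = v
                    arg = p
            if arg >= 0 and best > NEG_INF:
                F[n, s] = best + logphi[n, emit[s]]
                bp[n, s] = arg
    return F, bp
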