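"""Dynamic-programming kernels for local profile-HMM alignment.

The local model enters any match state with probability 1/M and exits
freely after any match state (unihit).  Scores are log-odds against the
null model, computed in natural-log space; emission score matrices carry a
21st column fixed at zero for the score-neutral symbol used for ambiguity
codes and masked regions.

Kernels are numba-compiled; a very large negative sentinel stands in for
log(0) so that arithmetic never produces NaNs.
"""

import math

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True, inline="always")
def _ladd(a, b):
    """log(exp(a) + exp(b)) with NEG as -inf sentinel."""
    if a < b:
        a, b = b, a
    if b < NEG / 2.0:
        return a
    return a + math.log1p(math.exp(b - a))


@njit(cache=True)
def viterbi_kernel(msc, isc, ltr, x, entry):
    """Best local alignment score and its span.

    Parameters: msc/isc are (M, 21) match/insert log-odds emission scores,
    ltr is (M, 7) log transition probabilities in the order
    MM, MI, MD, IM, II, DM, DD (row k = node k+1), x the encoded sequence
    (0..19 residues, 20 neutral), entry = log(1/M).

    Returns (score_nats, start_i, end_i, start_k, end_k) with 1-based
    residue and node coordinates, or score NEG when no alignment exists.
    """
    m = msc.shape[0]
    length = x.shape[0]
    vm = np.full((length + 1, m + 1), NEG)
    vi = np.full((length + 1, m + 1), NEG)
    vd = np.full((length + 1, m + 1), NEG)
    pm = np.zeros((length + 1, m + 1), dtype=np.int8)
    pi = np.zeros((length + 1, m + 1), dtype=np.int8)
    pd = np.zeros((length + 1, m + 1), dtype=np.int8)

    for i in range(1, length + 1):
        xi = x[i - 1]
        for k in range(1, m + 1):
            best = entry
            ptr = 0
            if k >= 2:
                s = vm[i - 1, k - 1] + ltr[k - 2, 0]
                if s > best:
                    best = s
                    ptr = 1
                s = vi[i - 1, k - 1] + ltr[k - 2, 3]
                if s > best:
                    best = s
                    ptr = 2
                s = vd[i - 1, k - 1] + ltr[k - 2, 5]
                if s > best:
                    best = s
                    ptr = 3
            vm[i, k] = msc[k - 1, xi] + best
            pm[i, k] = ptr
            if k < m:
                s_m = vm[i - 1, k] + ltr[k - 1, 1]
                s_i = vi[i - 1, k] + ltr[k - 1, 4]
                if s_m >= s_i:
                    vi[i, k] = isc[k - 1, xi] + s_m
                    pi[i, k] = 1
                else:
                    vi[i, k] = isc[k - 1, xi] + s_i
                    pi[i, k] = 2
        for k in range(2, m + 1):
            s_m = vm[i, k - 1] + ltr[k - 2, 2]
            s_d = vd[i, k - 1] + ltr[k - 2, 6]
            if s_m >= s_d:
                vd[i, k] = s_m
                pd[i, k] = 1
            else:
                vd[i, k] = s_d
                pd[i, k] = 3

    best = NEG
    bi = 0
    bk = 0
    for i in range(1, length + 1):
        for k in range(1, m + 1):
            if vm[i, k] > best:
                best = vm[i, k]
                bi = i
                bk = k
    if bi == 0:
        return NEG, 0, 0, 0, 0

    # Trace back to the entry point.
    i, k = bi, bk
    state = 1  # 1=M, 2=I, 3=D
    while True:
        if state == 1:
            ptr = pm[i, k]
            if ptr == 0:
                break
            state = ptr
            i -= 1
            k -= 1
        elif state == 2:
            state = pi[i, k]
            i -= 1
        else:
            state = pd[i, k]
            k -= 1
    return best, i, bi, k, bk


@njit(cache=True)
def forward_kernel(msc, isc, ltr, x, entry):
    """Log-sum over all local alignments (natural log), same model as
    :func:`viterbi_kernel`.  Returns NEG when no alignment exists."""
    m = msc.shape[0]
    length = x.shape[0]
    fm = np.full((length + 1, m + 1), NEG)
    fi = np.full((length + 1, m + 1), NEG)
    fd = np.full((length + 1, m + 1), NEG)
    total = NEG
    for i in range(1, length + 1):
        xi = x[i - 1]
        for k in range(1, m + 1):
            acc = entry
            if k >= 2:
                acc = _ladd(acc, fm[i - 1, k - 1] + ltr[k - 2, 0])
                acc = _ladd(acc, fi[i - 1, k - 1] + ltr[k - 2, 3])
                acc = _ladd(acc, fd[i - 1, k - 1] + ltr[k - 2, 5])
            fm[i, k] = msc[k - 1, xi] + acc
            total = _ladd(total, fm[i, k])
            if k < m:
                acc = _ladd(
                    fm[i - 1, k] + ltr[k - 1, 1], fi[i - 1, k] + ltr[k - 1, 4]
                )
                fi[i, k] = isc[k - 1, xi] + acc
        for k in range(2, m + 1):
            fd[i, k] = _ladd(
                fm[i, k - 1] + ltr[k - 2, 2], fd[i, k - 1] + ltr[k - 2, 6]
            )
    return total
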