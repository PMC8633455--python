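"""Numba kernels for secondary-structure and duplex minimum-free-energy folding.

The energy model is a simplified nearest-neighbour model: stacking energies for
adjacent base pairs, log-linear penalties for hairpin loops, bulges and internal
loops, and an affine multiloop cost.  All parameters arrive as arguments so the
kernels stay cache-friendly and the model stays overridable.

Base encoding: A=0, C=1, G=2, U=3.  Pair types: AU=0, UA=1, GC=2, CG=3, GU=4,
UG=5, non-pair=-1.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e18
MAXLOOP = 30
MIN_HAIRPIN = 3

# pair-type lookup, indexed [base_i, base_j]
PAIR_TYPE = -np.ones((4, 4), dtype=np.int8)
PAIR_TYPE[0, 3] = 0  # AU
PAIR_TYPE[3, 0] = 1  # UA
PAIR_TYPE[2, 1] = 2  # GC
PAIR_TYPE[1, 2] = 3  # CG
PAIR_TYPE[2, 3] = 4  # GU
PAIR_TYPE[3, 2] = 5  # UG


@njit(cache=True)
def _loop_energy(l1, l2, pt_outer, pt_inner, stack, hp_a, hp_b, bu_a, bu_b, in_a, in_b):
    """Energy of the loop closed by the outer pair and containing the inner pair."""
    if l1 == 0 and l2 == 0:
        return stack[pt_outer, pt_inner]
    if l1 + l2 > MAXLOOP:
        return INF
    if l1 == 0 or l2 == 0:
        return bu_a + bu_b * np.log(float(l1 + l2))
    return in_a + in_b * np.log((l1 + l2) / 2.0)


@njit(cache=True)
def fold_dp(seq, stack, hp_a, hp_b, bu_a, bu_b, in_a, in_b, ml_a, ml_b, ml_c):
    """Zuker-style MFE over one strand.  Returns (mfe, V, WM) matrices."""
    n = seq.shape[0]
    pt = np.empty((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(n):
            pt[i, j] = PAIR_TYPE[seq[i], seq[j]]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pt[i, j] >= 0:
                # hairpin closure
                best = hp_a + hp_b * np.log((j - i - 1) / 3.0)
                # interior / bulge / stack closure
                kmax = min(j - 1, i + MAXLOOP + 1)
                for k in range(i + 1, kmax + 1):
                    l1 = k - i - 1
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAXLOOP - l1))
                    for l in range(lmin, j):
                        if V[k, l] >= INF:
                            continue
                        e = _loop_energy(l1, j - l - 1, pt[i, j], pt[k, l],
                                         stack, hp_a, hp_b, bu_a, bu_b, in_a, in_b)
                        if V[k, l] + e < best:
                            best = V[k, l] + e
                # multiloop closure: >=2 branches inside
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        e = ml_a + ml_b + WM[i + 1, k] + WM[k + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM: segment holding >=1 multiloop branch
            best = INF
            if V[i, j] < INF:
                best = V[i, j] + ml_b
            if WM[i + 1, j] < INF and WM[i + 1, j] + ml_c < best:
                best = WM[i + 1, j] + ml_c
            if WM[i, j - 1] < INF and WM[i, j - 1] + ml_c < best:
                best = WM[i, j - 1] + ml_c
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    if WM[i, k - 1] + WM[k, j] < best:
                        best = WM[i, k - 1] + WM[k, j]
            WM[i, j] = best
    # external loop
    W = np.zeros(n)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for k in range(0, j):
            if V[k, j] < INF:
                left = W[k - 1] if k > 0 else 0.0
                if left + V[k, j] < best:
                    best = left + V[k, j]
        if V[0, j] < INF and V[0, j] < best:
            best = V[0, j]
        W[j] = best
    mfe = min(0.0, W[n - 1]) if n > 0 else 0.0
    return mfe, V, WM


@njit(cache=True)
def duplex_dp(a, b, stack, bu_a, bu_b, in_a, in_b):
    """Intermolecular MFE: antiparallel monotone pairing of a (5'->3') vs b.

    E[i, j] = best energy of a hybrid whose rightmost-in-a pair is (i, j).
    Returns (mfe, E).
    """
    n = a.shape[0]
    m = b.shape[0]
    E = np.full((n, m), INF)
    mfe = 0.0
    for i in range(n):
        for j in range(m - 1, -1, -1):
            if PAIR_TYPE[a[i], b[j]] < 0:
                continue
            best = 0.0  # (i, j) opens the duplex
            imin = max(0, i - MAXLOOP - 1)
            for ip in range(imin, i):
                l1 = i - ip - 1
                jmax = min(m - 1, j + 1 + (MAXLOOP - l1))
                for jp in range(j + 1, jmax + 1):
                    if E[ip, jp] >= INF:
                        continue
                    l2 = jp - j - 1
                    if l1 == 0 and l2 == 0:
                        e = stack[PAIR_TYPE[a[ip], b[jp]], PAIR_TYPE[a[i], b[j]]]
                    elif l1 == 0 or l2 == 0:
                        e = bu_a + bu_b * np.log(float(l1 + l2))
                    else:
                        e = in_a + in_b * np.log((l1 + l2) / 2.0)
                    if E[ip, jp] + e < best:
                        best = E[ip, jp] + e
            E[i, j] = best
            if best < mfe:
                mfe = best
    return mfe, E
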