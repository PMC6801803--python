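"""Numba kernels for the nearest-neighbour folding recursions.

All kernels work on 0-based integer-encoded sequences (A=0, C=1, G=2, U=3)
and a precomputed pair-type matrix ``pt`` with ``pt[i, j]`` in 0..5 for the
six canonical pairs (CG, GC, GU, UG, AU, UA) and -1 otherwise.  Probing data
enter through ``dg``, a per-nucleotide pseudo-energy (kcal/mol) added for
every nucleotide of every helix stack it participates in; nucleotides in the
interior of a helix therefore receive the term twice (once per enclosing
stack), which is the convention the pseudo-energy slope/intercept defaults
were trained for.

Grammar (non-redundant, so the same recursions serve the minimum, the
complete-suboptimal enumeration, and the partition function):

    V(i,j)  = energy of the best structure closed by pair (i,j)
            = min( hairpin(i,j),
                   interior(i,j,k,l) + V(k,l)      [u1+u2 <= MAXLOOP],
                   a + b + min_k M(i+1,k-1) + M1(k,j-1) )
    M1(i,j) = min( M1(i,j-1), V(i,j) + b )          [branch starts at i]
    M(i,j)  = min_k min( M1(k,j), M(i,k-1) + M1(k,j) )  [>=1 branch]
    W(j)    = min( W(j-1), min_i W(i-1) + V(i,j) )      [exterior]

with multibranch energy a + b per branch (per-unpaired coefficient c = 0).
Hairpin loops have >= 3 unpaired nucleotides; interior/bulge loops are
capped at MAXLOOP = 30 unpaired nucleotides (standard search restriction).
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e18
MAXLOOP = 30


@njit(cache=True)
def _interior_energy(pti, ptk, u1, u2, i, j, k, l, dg, stack,
                     bulge_tab, internal_tab, ninio_m, ninio_max):
    """Energy of the interior loop/stack closed by (i,j) with inner (k,l)."""
    if u1 == 0 and u2 == 0:
        return (stack[pti, ptk]
                + dg[i] + dg[j] + dg[k] + dg[l])
    if u1 == 0 or u2 == 0:
        return bulge_tab[u1 + u2]
    d = u1 - u2
    if d < 0:
        d = -d
    asym = ninio_m * d
    if asym > ninio_max:
        asym = ninio_max
    return internal_tab[u1 + u2] + asym


@njit(cache=True)
def fill_mfe(pt, dg, stack, hairpin_tab, bulge_tab, internal_tab,
             ninio_m, ninio_max, ml_a, ml_b):
    """Fill V, M, M1 and the exterior array W.  Returns (V, M, M1, W)."""
    n = pt.shape[0]
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)
    M1 = np.full((n, n), INF)
    W = np.zeros(n + 1)  # W[j+1] = best energy of [0..j]; W[0] = 0

    for d in range(4, n):
        for i in range(0, n - d):
            j = i + d
            if pt[i, j] >= 0:
                best = hairpin_tab[j - i - 1]
                # interior loops / stacks
                kmax = i + MAXLOOP + 1
                if kmax > j - 5:
                    kmax = j - 5
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    lmin = j - 1 - (MAXLOOP - u1)
                    if lmin < k + 4:
                        lmin = k + 4
                    for l in range(j - 1, lmin - 1, -1):
                        if pt[k, l] < 0:
                            continue
                        if V[k, l] >= INF:
                            continue
                        e = _interior_energy(pt[i, j], pt[k, l], u1,
                                             j - l - 1, i, j, k, l, dg, stack,
                                             bulge_tab, internal_tab,
                                             ninio_m, ninio_max)
                        cand = e + V[k, l]
                        if cand < best:
                            best = cand
                    # multibranch closure: last branch starts at k
                for k in range(i + 2, j - 4):
                    if M[i + 1, k - 1] < INF and M1[k, j - 1] < INF:
                        cand = ml_a + ml_b + M[i + 1, k - 1] + M1[k, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # M1
            b1 = M1[i, j - 1]
            if pt[i, j] >= 0 and V[i, j] + ml_b < b1:
                b1 = V[i, j] + ml_b
            M1[i, j] = b1
            # M
            bm = INF
            for k in range(i, j + 1):
                m1 = M1[k, j]
                if m1 >= INF:
                    continue
                if m1 < bm:
                    bm = m1
                if k > i and M[i, k - 1] < INF:
                    cand = M[i, k - 1] + m1
                    if cand < bm:
                        bm = cand
            M[i, j] = bm

    for j in range(n):
        best = W[j]  # j unpaired
        for i in range(0, j - 3):
            if V[i, j] < INF:
                cand = W[i] + V[i, j]
                if cand < best:
                    best = cand
        W[j + 1] = best
    return V, M, M1, W


@njit(cache=True)
def traceback_mfe(pt, dg, stack, hairpin_tab, bulge_tab, internal_tab,
                  ninio_m, ninio_max, ml_a, ml_b, V, M, M1, W):
    """Deterministic traceback.  Ties prefer unpaired, then the candidate
    encountered first in a fixed scan order.  Returns partner array
    (partner[i] = j or -1)."""
    n = pt.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    eps = 1e-9
    # stack of intervals: (kind, i, j); kinds: 0=EXT upto j, 1=V, 2=M, 3=M1
    st_kind = np.empty(4 * n + 8, dtype=np.int64)
    st_i = np.empty(4 * n + 8, dtype=np.int64)
    st_j = np.empty(4 * n + 8, dtype=np.int64)
    top = 0
    st_kind[top] = 0
    st_i[top] = 0
    st_j[top] = n - 1
    top += 1
    while top > 0:
        top -= 1
        kind = st_kind[top]
        i = st_i[top]
        j = st_j[top]
        if kind == 0:
            # exterior [0..j]
            while j >= 0:
                if W[j + 1] >= W[j] - eps:
                    j -= 1
                    continue
                found = False
                for k in range(0, j - 3):
                    if V[k, j] < INF and W[k] + V[k, j] <= W[j + 1] + eps:
                        partner[k] = j
                        partner[j] = k
                        st_kind[top] = 1
                        st_i[top] = k
                        st_j[top] = j
                        top += 1
                        j = k - 1
                        found = True
                        break
                if not found:
                    j -= 1
        elif kind == 1:
            val = V[i, j]
            if hairpin_tab[j - i - 1] <= val + eps:
                continue
            done = False
            kmax = i + MAXLOOP + 1
            if kmax > j - 5:
                kmax = j - 5
            for k in range(i + 1, kmax + 1):
                u1 = k - i - 1
                lmin = j - 1 - (MAXLOOP - u1)
                if lmin < k + 4:
                    lmin = k + 4
                for l in range(j - 1, lmin - 1, -1):
                    if pt[k, l] < 0 or V[k, l] >= INF:
                        continue
                    e = _interior_energy(pt[i, j], pt[k, l], u1, j - l - 1,
                                         i, j, k, l, dg, stack, bulge_tab,
                                         internal_tab, ninio_m, ninio_max)
                    if e + V[k, l] <= val + eps:
                        partner[k] = l
                        partner[l] = k
                        st_kind[top] = 1
                        st_i[top] = k
                        st_j[top] = l
                        top += 1
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            for k in range(i + 2, j - 4):
                if M[i + 1, k - 1] < INF and M1[k, j - 1] < INF:
                    if ml_a + ml_b + M[i + 1, k - 1] + M1[k, j - 1] <= val + eps:
                        st_kind[top] = 2
                        st_i[top] = i + 1
                        st_j[top] = k - 1
                        top += 1
                        st_kind[top] = 3
                        st_i[top] = k
                        st_j[top] = j - 1
                        top += 1
                        break
        elif kind == 2:
            val = M[i, j]
            for k in range(i, j + 1):
                m1 = M1[k, j]
                if m1 >= INF:
                    continue
                if m1 <= val + eps:
                    st_kind[top] = 3
                    st_i[top] = k
                    st_j[top] = j
                    top += 1
                    break
                if k > i and M[i, k - 1] < INF and M[i, k - 1] + m1 <= val + eps:
                    st_kind[top] = 2
                    st_i[top] = i
                    st_j[top] = k - 1
                    top += 1
                    st_kind[top] = 3
                    st_i[top] = k
                    st_j[top] = j
                    top += 1
                    break
        else:
            # M1: trailing unpaired then the branch
            while M1[i, j - 1] <= M1[i, j] + eps:
                j -= 1
            partner[i] = j
            partner[j] = i
            st_kind[top] = 1
            st_i[top] = i
            st_j[top] = j
            top += 1
    return partner


@njit(cache=True)
def fill_partition(pt, dg, stack, hairpin_tab, bulge_tab, internal_tab,
                   ninio_m, ninio_max, ml_a, ml_b, RT, spow):
    """Inside pass of the McCaskill recursion (scaled).

    ``spow[m]`` must hold ``s**-m`` for the per-nucleotide scaling factor s.
    Returns (Qb, QM, QM1, Qf, Qbk) where Qf[j] is the scaled partition
    function of the prefix [0..j-1] (Qf[0] = 1) and Qbk[i] of the suffix
    [i..n-1] (Qbk[n] = 1).
    """
    n = pt.shape[0]
    Qb = np.zeros((n, n))
    QM = np.zeros((n, n))
    QM1 = np.zeros((n, n))
    for d in range(0, n):
        for i in range(0, n - d):
            j = i + d
            if d >= 4 and pt[i, j] >= 0:
                q = np.exp(-hairpin_tab[j - i - 1] / RT) * spow[j - i + 1]
                kmax = i + MAXLOOP + 1
                if kmax > j - 5:
                    kmax = j - 5
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    lmin = j - 1 - (MAXLOOP - u1)
                    if lmin < k + 4:
                        lmin = k + 4
                    for l in range(j - 1, lmin - 1, -1):
                        if pt[k, l] < 0 or Qb[k, l] <= 0.0:
                            continue
                        e = _interior_energy(pt[i, j], pt[k, l], u1,
                                             j - l - 1, i, j, k, l, dg, stack,
                                             bulge_tab, internal_tab,
                                             ninio_m, ninio_max)
                        q += np.exp(-e / RT) * Qb[k, l] * spow[(j - i) - (l - k)]
                qml = 0.0
                for k in range(i + 2, j - 4):
                    if QM[i + 1, k - 1] > 0.0 and QM1[k, j - 1] > 0.0:
                        qml += QM[i + 1, k - 1] * QM1[k, j - 1]
                q += np.exp(-(ml_a + ml_b) / RT) * spow[2] * qml
                Qb[i, j] = q
            # QM1
            q1 = Qb[i, j] * np.exp(-ml_b / RT)
            if j > i:
                q1 += QM1[i, j - 1] * spow[1]
            QM1[i, j] = q1
            # QM
            qm = 0.0
            for k in range(i, j + 1):
                if QM1[k, j] <= 0.0:
                    continue
                lead = spow[k - i]
                if k > i:
                    lead += QM[i, k - 1]
                qm += lead * QM1[k, j]
            QM[i, j] = qm

    Qf = np.empty(n + 1)
    Qf[0] = 1.0
    for j in range(n):
        q = Qf[j] * spow[1]
        for i in range(0, j - 3):
            if Qb[i, j] > 0.0:
                q += Qf[i] * Qb[i, j]
        Qf[j + 1] = q
    Qbk = np.empty(n + 1)
    Qbk[n] = 1.0
    for i in range(n - 1, -1, -1):
        q = Qbk[i + 1] * spow[1]
        for l in range(i + 4, n):
            if Qb[i, l] > 0.0:
                q += Qb[i, l] * Qbk[l + 1]
        Qbk[i] = q
    return Qb, QM, QM1, Qf, Qbk


@njit(cache=True)
def pair_probabilities(pt, dg, stack, hairpin_tab, bulge_tab, internal_tab,
                       ninio_m, ninio_max, ml_a, ml_b, RT, spow,
                       Qb, QM, QM1, Qf, Qbk):
    """Outside pass: equilibrium probability of every pair (i, j).

    Processes spans in decreasing order; running tables D and E accumulate,
    for every finalized enclosing pair (k, l), the multibranch weight seen
    by a branch ending at column j with (D) or without (E) further branches
    between k and the branch start.  This keeps the multiloop outside sum
    at O(n^3) overall.
    """
    n = pt.shape[0]
    Qo = np.zeros((n, n))
    P = np.zeros((n, n))
    D = np.zeros((n, n))
    E = np.zeros((n, n))
    Q = Qf[n]
    w_close = np.exp(-(ml_a + 2.0 * ml_b) / RT)
    for d in range(n - 1, 3, -1):
        for i in range(0, n - d):
            j = i + d
            if pt[i, j] < 0 or Qb[i, j] <= 0.0:
                continue
            q = Qf[i] * Qbk[j + 1]
            # enclosed in an interior loop of (k, l)
            kmin = i - MAXLOOP - 1
            if kmin < 0:
                kmin = 0
            for k in range(kmin, i):
                u1 = i - k - 1
                lmax = j + 1 + (MAXLOOP - u1)
                if lmax > n - 1:
                    lmax = n - 1
                for l in range(j + 1, lmax + 1):
                    if pt[k, l] < 0 or Qo[k, l] <= 0.0:
                        continue
                    e = _interior_energy(pt[k, l], pt[i, j], u1, l - j - 1,
                                         k, l, i, j, dg, stack, bulge_tab,
                                         internal_tab, ninio_m, ninio_max)
                    q += Qo[k, l] * np.exp(-e / RT) * spow[u1 + (l - j - 1) + 2]
            # branch of a multiloop
            for k in range(0, i):
                if D[k, j] > 0.0 and i - k >= 2 and QM[k + 1, i - 1] > 0.0:
                    q += QM[k + 1, i - 1] * D[k, j]
                if E[k, j] > 0.0:
                    q += spow[i - k - 1] * E[k, j]
            Qo[i, j] = q
            P[i, j] = Qb[i, j] * q / Q
        # fold this span's pairs into D and E as enclosing multiloop pairs
        for i in range(0, n - d):
            j = i + d
            if Qo[i, j] <= 0.0:
                continue
            C = Qo[i, j] * w_close * spow[2]
            for jj in range(i + 1, j):
                qmr = 0.0
                if jj + 1 <= j - 1:
                    qmr = QM[jj + 1, j - 1]
                D[i, jj] += C * (spow[j - jj - 1] + qmr)
                if qmr > 0.0:
                    E[i, jj] += C * qmr
    return P
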