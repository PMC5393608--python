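"""Compiled numeric kernels (numba): distances, NJ agglomeration, alignment.

Sequences are encoded as uint8: A=0, C=1, G=2, T=3, missing (N/-/?) = 255.
With this coding a substitution is a transition iff ``a ^ b == 2``
(A<->G, C<->T) and a transversion otherwise.

For all-pairs distance matrices the codes are bit-packed into three uint64
planes per sequence (low code bit, high code bit, validity) so per-pair
site counts reduce to XOR/AND plus popcounts - the workhorse of the
bootstrap, which rebuilds the matrix for every column resample.
"""

from __future__ import annotations

import numpy as np
from numba import njit

CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    CODE[ord(base)] = i

MODEL_P, MODEL_JC, MODEL_K2P = 0, 1, 2
MODEL_IDS = {"p": MODEL_P, "jc": MODEL_JC, "k2p": MODEL_K2P}


def encode(residues: str) -> np.ndarray:
    """Encode a residue string to the uint8 alphabet above."""
    return CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def pairwise_counts(a, b):
    """(comparable, transitions, transversions) over sites where both are ACGT."""
    comp = 0
    ts = 0
    tv = 0
    for k in range(a.size):
        x = a[k]
        y = b[k]
        if x < 4 and y < 4:
            comp += 1
            if x != y:
                if x ^ y == 2:
                    ts += 1
                else:
                    tv += 1
    return comp, ts, tv


@njit(cache=True, inline="always")
def _popcount64(x):
    x = x - ((x >> 1) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + (
        (x >> 2) & np.uint64(0x3333333333333333)
    )
    x = (x + (x >> 4)) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> np.uint64(56)


@njit(cache=True)
def pack_codes(codes):
    """Pack an (n, L) uint8 code matrix into (c0, c1, valid) uint64 planes."""
    n, L = codes.shape
    W = (L + 63) // 64
    c0 = np.zeros((n, W), np.uint64)
    c1 = np.zeros((n, W), np.uint64)
    v = np.zeros((n, W), np.uint64)
    for i in range(n):
        for k in range(L):
            c = codes[i, k]
            if c < 4:
                w = k >> 6
                bit = np.uint64(k & 63)
                v[i, w] |= np.uint64(1) << bit
                c0[i, w] |= np.uint64(c & 1) << bit
                c1[i, w] |= np.uint64((c >> 1) & 1) << bit
    return c0, c1, v


@njit(cache=True, inline="always")
def _model_distance(comp, ts, tv, model):
    """Distance under the chosen model; NaN when undefined."""
    if comp == 0:
        return np.nan
    p = (ts + tv) / comp
    if model == 0:
        return p + 0.0
    if model == 1:
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0.0:
            return np.nan
        return -0.75 * np.log(arg)
    P = ts / comp
    Q = tv / comp
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return np.nan
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


@njit(cache=True)
def packed_distance_matrix(c0, c1, v, model):
    """Full symmetric distance matrix from bit-packed code planes."""
    n, W = v.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = 0
            ts = 0
            diff = 0
            for w in range(W):
                vw = v[i, w] & v[j, w]
                d0 = c0[i, w] ^ c0[j, w]
                d1 = c1[i, w] ^ c1[j, w]
                comp += _popcount64(vw)
                diff += _popcount64((d0 | d1) & vw)
                ts += _popcount64(d1 & ~d0 & vw)
            d = _model_distance(float(comp), float(ts), float(diff - ts), model)
            out[i, j] = d
            out[j, i] = d
    return out


def distance_matrix_kernel(codes: np.ndarray, model: int) -> np.ndarray:
    """All-pairs distances from an (n, L) uint8 code matrix."""
    c0, c1, v = pack_codes(np.ascontiguousarray(codes))
    return packed_distance_matrix(c0, c1, v, model)


# ---------------------------------------------------------------------------
# NJ agglomeration
# ---------------------------------------------------------------------------

@njit(cache=True)
def nj_join_sequence(D0, rank):
    """Saitou-Nei joins with deterministic tie-breaking.

    ``rank[i]`` is the lexicographic rank of taxon i's id; a cluster's key
    is the smallest rank among its leaves, and Q-ties are broken by the
    smallest (key_i, key_j) pair.

    Returns (joins, join_lens, final_slots, final_lens): ``joins`` holds the
    cluster ids merged at each pair step (initial clusters 0..n-1, new ones
    numbered onward); the final three clusters form the trifurcation.
    """
    n = D0.shape[0]
    D = D0.copy()
    active = np.ones(n, np.bool_)
    cid = np.arange(n)
    key = rank.copy()
    n_steps = n - 3
    joins = np.empty((n_steps, 2), np.int64)
    join_lens = np.empty((n_steps, 2))
    next_id = n
    m = n
    step = 0
    r = np.zeros(n)
    while m > 3:
        for i in range(n):
            if active[i]:
                s = 0.0
                for j in range(n):
                    if active[j]:
                        s += D[i, j]
                r[i] = s
        best = np.inf
        bi = -1
        bj = -1
        bk1 = np.int64(2**62)
        bk2 = np.int64(2**62)
        coef = m - 2.0
        for i in range(n):
            if not active[i]:
                continue
            for j in range(i + 1, n):
                if not active[j]:
                    continue
                q = coef * D[i, j] - r[i] - r[j]
                if q < best:
                    take = True
                elif q == best:
                    k1 = min(key[i], key[j])
                    k2 = max(key[i], key[j])
                    take = k1 < bk1 or (k1 == bk1 and k2 < bk2)
                else:
                    take = False
                if take:
                    best = q
                    bi = i
                    bj = j
                    bk1 = min(key[i], key[j])
                    bk2 = max(key[i], key[j])
        li = 0.5 * D[bi, bj] + (r[bi] - r[bj]) / (2.0 * coef)
        lj = D[bi, bj] - li
        if li < 0.0:
            li = 0.0
        if lj < 0.0:
            lj = 0.0
        joins[step, 0] = cid[bi]
        joins[step, 1] = cid[bj]
        join_lens[step, 0] = li
        join_lens[step, 1] = lj
        dij = D[bi, bj]
        for t in range(n):
            if active[t] and t != bi and t != bj:
                nd = 0.5 * (D[bi, t] + D[bj, t] - dij)
                D[bi, t] = nd
                D[t, bi] = nd
        active[bj] = False
        cid[bi] = next_id
        if key[bj] < key[bi]:
            key[bi] = key[bj]
        next_id += 1
        m -= 1
        step += 1
    rem = np.empty(3, np.int64)
    c = 0
    for i in range(n):
        if active[i]:
            rem[c] = i
            c += 1
    d01 = D[rem[0], rem[1]]
    d02 = D[rem[0], rem[2]]
    d12 = D[rem[1], rem[2]]
    final_lens = np.empty(3)
    final_lens[0] = max(0.5 * (d01 + d02 - d12), 0.0)
    final_lens[1] = max(0.5 * (d01 + d12 - d02), 0.0)
    final_lens[2] = max(0.5 * (d02 + d12 - d01), 0.0)
    final_ids = np.empty(3, np.int64)
    for c in range(3):
        final_ids[c] = cid[rem[c]]
    return joins, join_lens, final_ids, final_lens


# ---------------------------------------------------------------------------
# local alignment
# ---------------------------------------------------------------------------

@njit(cache=True)
def sw_score(a, b, match, mismatch, gap_open, gap_extend, band):
    """Score-only Smith-Waterman with affine gaps (Gotoh), optionally banded.

    ``gap_open`` is the score of the first gap position (blast-style).
    ``band < 0`` runs the full dynamic program.  A banded run restricts the
    alignment path to diagonals within ``band`` of the main diagonal
    (widened by the length difference) and therefore returns a lower bound
    on the unbanded score; the two agree whenever the optimal path stays in
    the band, which holds for near-full-length homologous sequences with
    small indels.
    """
    n = a.size
    m = b.size
    if n == 0 or m == 0:
        return 0.0
    if band < 0:
        lo_d = -n
        hi_d = m
    else:
        lo_d = -band + min(0, m - n)
        hi_d = band + max(0, m - n)
    H = np.zeros(m + 1)
    E = np.full(m + 1, -1e18)
    best = 0.0
    for i in range(1, n + 1):
        jlo = max(1, i + lo_d)
        jhi = min(m, i + hi_d)
        if jlo > jhi:
            continue
        diag = H[jlo - 1]
        F = -1e18
        for j in range(jlo, jhi + 1):
            E[j] = max(H[j] + gap_open, E[j] + gap_extend)
            F = max(H[j - 1] + gap_open, F + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = diag + s
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0.0:
                h = 0.0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
        # column jlo-1 leaves the band for all later rows: reset it to the
        # local-alignment floor so stale values cannot seed spurious paths
        H[jlo - 1] = 0.0
        E[jlo - 1] = -1e18
    return best


@njit(cache=True)
def sw_score_linear(a, b, match, mismatch, gap, band):
    """Smith-Waterman with a linear gap penalty (the open == extend case).

    Equivalent to :func:`sw_score` with ``gap_open == gap_extend == gap``
    but without the affine bookkeeping; same banding semantics.
    """
    n = a.size
    m = b.size
    if n == 0 or m == 0:
        return 0.0
    if band < 0:
        lo_d = -n
        hi_d = m
    else:
        lo_d = -band + min(0, m - n)
        hi_d = band + max(0, m - n)
    H = np.zeros(m + 1)
    best = 0.0
    for i in range(1, n + 1):
        jlo = max(1, i + lo_d)
        jhi = min(m, i + hi_d)
        if jlo > jhi:
            continue
        diag = H[jlo - 1]
        left = 0.0
        for j in range(jlo, jhi + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = diag + s
            up = H[j] + gap
            if up > h:
                h = up
            lf = left + gap
            if lf > h:
                h = lf
            if h < 0.0:
                h = 0.0
            diag = H[j]
            H[j] = h
            left = h
            if h > best:
                best = h
        H[jlo - 1] = 0.0
    return best
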