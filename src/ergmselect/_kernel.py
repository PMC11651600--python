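"""Numba hot loop for Metropolis-Hastings dyad-toggle sampling.

The Python change statistics in :mod:`ergmselect.terms` are authoritative;
this module mirrors them on a dense adjacency matrix so chains run at
compiled speed.  Agreement between the two implementations is enforced by
randomized tests.

State is (A, deg): a dense symmetric uint8 adjacency matrix and the degree
vector.  Randomness is an explicit xorshift128+ state array, so chains are
reproducible across platforms and numba versions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# term codes (must match ergmselect.terms.KINDS order used in model compilation)
CODE = {
    "edges": 0,
    "kstar": 1,
    "dsp": 2,
    "esp": 3,
    "nsp": 4,
    "triangle": 5,
    "isolates": 6,
    "sociality": 7,
    "degree_cross_product": 8,
    "degree_popularity": 9,
    "gwesp": 10,
    "gwnsp": 11,
    "gwdsp": 12,
    "gwdegree": 13,
    "nodecov": 14,
    "absdiff": 15,
}


@njit(cache=False)
def _unif(state):
    """xorshift128+ uniform in [0, 1)."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 = s1 ^ (s1 << np.uint64(23))
    state[1] = s1 ^ s0 ^ (s1 >> np.uint64(17)) ^ (s0 >> np.uint64(26))
    return float((state[1] + s0) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


def make_rng_state(seed: int) -> np.ndarray:
    """Expand a Python integer seed into a nonzero xorshift128+ state."""
    state = np.random.SeedSequence(seed).generate_state(2, np.uint64)
    if state[0] == 0 and state[1] == 0:  # pragma: no cover
        state[1] = np.uint64(0x9E3779B97F4A7C15)
    return state


@njit(cache=False)
def _comb_f(n, k):
    """C(n, k) as a float; 0 outside the valid range."""
    if k < 0 or k > n:
        return 0.0
    if k == 0:
        return 1.0
    out = 1.0
    for t in range(k):
        out = out * (n - t) / (t + 1)
    return out


@njit(cache=False)
def _gww(k, tau):
    if k <= 0:
        return 0.0
    return np.exp(tau) * (1.0 - (1.0 - np.exp(-tau)) ** k)


@njit(cache=False)
def _change_up(A, deg, x, codes, kparam, fparam, covidx, offsets, out, i, j):
    """Change statistics for adding edge (i, j); requires A[i, j] == 0."""
    n = A.shape[0]
    for q in range(out.shape[0]):
        out[q] = 0.0
    cn = 0
    for v in range(n):
        if A[i, v] == 1 and A[j, v] == 1:
            cn += 1
    di = deg[i]
    dj = deg[j]
    for t in range(codes.shape[0]):
        c = codes[t]
        off = offsets[t]
        if c == 0:
            out[off] = 1.0
        elif c == 1:
            k = kparam[t]
            out[off] = _comb_f(di, k - 1) + _comb_f(dj, k - 1)
        elif c == 2 or c == 3 or c == 4:
            k = kparam[t]
            ddsp = 0
            desp = 0
            for rep in range(2):
                a = i if rep == 0 else j
                b = j if rep == 0 else i
                for w in range(n):
                    if w == a or A[b, w] == 0:
                        continue
                    cc = 0
                    for v in range(n):
                        if A[a, v] == 1 and A[w, v] == 1:
                            cc += 1
                    d = (1 if cc + 1 == k else 0) - (1 if cc == k else 0)
                    ddsp += d
                    if A[a, w] == 1:
                        desp += d
            if cn == k:
                desp += 1
            if c == 2:
                out[off] = float(ddsp)
            elif c == 3:
                out[off] = float(desp)
            else:
                out[off] = float(ddsp - desp)
        elif c == 5:
            out[off] = float(cn)
        elif c == 6:
            acc = 0.0
            if di == 0:
                acc += 1.0
            if dj == 0:
                acc += 1.0
            out[off] = -acc
        elif c == 7:
            if i >= 1:
                out[off + i - 1] = 1.0
            if j >= 1:
                out[off + j - 1] = 1.0
        elif c == 8:
            m = 0
            S = 0.0
            for a in range(n):
                for b in range(a + 1, n):
                    if A[a, b] == 1:
                        m += 1
                        S += deg[a] * deg[b]
            ds = 0.0
            for v in range(n):
                if A[i, v] == 1:
                    ds += deg[v]
                if A[j, v] == 1:
                    ds += deg[v]
            S_new = S + ds + (di + 1.0) * (dj + 1.0)
            old = S / m if m > 0 else 0.0
            out[off] = S_new / (m + 1) - old
        elif c == 9:
            out[off] = (
                (di + 1.0) ** 1.5 - float(di) ** 1.5 + (dj + 1.0) ** 1.5 - float(dj) ** 1.5
            )
        elif c == 10 or c == 11 or c == 12:
            tau = fparam[t]
            dgwdsp = 0.0
            dgwesp = 0.0
            for rep in range(2):
                a = i if rep == 0 else j
                b = j if rep == 0 else i
                for w in range(n):
                    if w == a or A[b, w] == 0:
                        continue
                    cc = 0
                    for v in range(n):
                        if A[a, v] == 1 and A[w, v] == 1:
                            cc += 1
                    d = _gww(cc + 1, tau) - _gww(cc, tau)
                    dgwdsp += d
                    if A[a, w] == 1:
                        dgwesp += d
            dgwesp += _gww(cn, tau)
            if c == 12:
                out[off] = dgwdsp
            elif c == 10:
                out[off] = dgwesp
            else:
                out[off] = dgwdsp - dgwesp
        elif c == 13:
            tau = fparam[t]
            out[off] = (
                _gww(di + 1, tau) - _gww(di, tau) + _gww(dj + 1, tau) - _gww(dj, tau)
            )
        elif c == 14:
            out[off] = x[i, covidx[t]] + x[j, covidx[t]]
        elif c == 15:
            out[off] = abs(x[i, covidx[t]] - x[j, covidx[t]])


@njit(cache=False)
def advance(A, deg, x, codes, kparam, fparam, covidx, offsets, theta, stats, n_steps, state, delta):
    """Run ``n_steps`` Metropolis toggles in place; stats updated incrementally."""
    n = A.shape[0]
    dim = theta.shape[0]
    for _ in range(n_steps):
        i = int(_unif(state) * n)
        if i >= n:
            i = n - 1
        j = int(_unif(state) * (n - 1))
        if j >= n - 1:
            j = n - 2
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        if A[i, j] == 1:
            A[i, j] = 0
            A[j, i] = 0
            deg[i] -= 1
            deg[j] -= 1
            _change_up(A, deg, x, codes, kparam, fparam, covidx, offsets, delta, i, j)
            lr = 0.0
            for q in range(dim):
                lr -= theta[q] * delta[q]
            if lr >= 0.0 or _unif(state) < np.exp(lr):
                for q in range(dim):
                    stats[q] -= delta[q]
            else:
                A[i, j] = 1
                A[j, i] = 1
                deg[i] += 1
                deg[j] += 1
        else:
            _change_up(A, deg, x, codes, kparam, fparam, covidx, offsets, delta, i, j)
            lr = 0.0
            for q in range(dim):
                lr += theta[q] * delta[q]
            if lr >= 0.0 or _unif(state) < np.exp(lr):
                A[i, j] = 1
                A[j, i] = 1
                deg[i] += 1
                deg[j] += 1
                for q in range(dim):
                    stats[q] += delta[q]
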