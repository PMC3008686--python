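"""Compiled forward/backward recursions for the motif HMM.

The machine's structure (four indicator-emission background states plus
deterministic motif chains) reduces each forward step to a handful of
per-sequence multiply-adds; these kernels run that recurrence over a whole
same-length sequence batch in one compiled sweep.  A pure-numpy fallback in
:mod:`hmmenrich.hmm` implements the identical recurrence and the two are
cross-checked in the test suite (and both against exhaustive path
enumeration).

Layout conventions: ``Ebg`` is (T, n, 4) background emissions (1 for the
matching base or N), ``Em`` is (T, n, nbr*L) motif-state emissions with the
branches concatenated (forward chain first, reverse-complement chain second),
``entries`` the per-branch entry probabilities.  Scaling is per position;
``z`` holds the scale factors so log P = sum log z.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAS_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAS_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def forward_kernel(Ebg, Em, entries, c, trans, init, keep_alphas):
    """Scaled forward pass; returns (loglik, alphas_bg, z).

    ``alphas_bg``/``z`` are filled only when ``keep_alphas`` (the backward
    pass needs them); otherwise they are 1-element placeholders.
    """
    T, n, _ = Ebg.shape
    M = Em.shape[2]
    nbr = entries.shape[0]
    L = M // nbr if nbr > 0 else 0

    loglik = np.zeros(n)
    if keep_alphas:
        alphas_bg = np.empty((T, n, 4))
        z = np.empty((T, n))
    else:
        alphas_bg = np.empty((1, 1, 4))
        z = np.empty((1, 1))

    a_bg = np.empty((n, 4))
    a_m = np.zeros((n, M))
    new_bg = np.empty(4)
    new_m = np.empty(M)

    for i in range(n):
        tot = 0.0
        for b in range(4):
            v = c * init[b] * Ebg[0, i, b]
            a_bg[i, b] = v
            tot += v
        for br in range(nbr):
            v = entries[br] * Em[0, i, br * L]
            a_m[i, br * L] = v
            tot += v
        for b in range(4):
            a_bg[i, b] /= tot
        for br in range(nbr):
            a_m[i, br * L] /= tot
        loglik[i] += np.log(tot)
        if keep_alphas:
            z[0, i] = tot
            for b in range(4):
                alphas_bg[0, i, b] = a_bg[i, b]

    for t in range(1, T):
        for i in range(n):
            exit_mass = 0.0
            bg_sum = 0.0
            for br in range(nbr):
                exit_mass += a_m[i, br * L + L - 1]
            for b in range(4):
                bg_sum += a_bg[i, b]
            tot = 0.0
            for b in range(4):
                acc = exit_mass * init[b]
                for a in range(4):
                    acc += a_bg[i, a] * c * trans[a, b]
                acc *= Ebg[t, i, b]
                new_bg[b] = acc
                tot += acc
            for br in range(nbr):
                off = br * L
                for j in range(L - 1, 0, -1):
                    v = a_m[i, off + j - 1] * Em[t, i, off + j]
                    new_m[off + j] = v
                    tot += v
                v = bg_sum * entries[br] * Em[t, i, off]
                new_m[off] = v
                tot += v
            for b in range(4):
                a_bg[i, b] = new_bg[b] / tot
            for k in range(M):
                a_m[i, k] = new_m[k] / tot
            loglik[i] += np.log(tot)
            if keep_alphas:
                z[t, i] = tot
                for b in range(4):
                    alphas_bg[t, i, b] = a_bg[i, b]
    return loglik, alphas_bg, z


@njit(cache=True)
def backward_counts_kernel(Ebg, Em, entries, c, trans, init, alphas_bg, z):
    """Backward pass accumulating EM entry/out counts; returns (num, den)."""
    T, n, _ = Ebg.shape
    M = Em.shape[2]
    nbr = entries.shape[0]
    L = M // nbr if nbr > 0 else 0

    num = np.zeros(n)
    den = np.ones(n)
    b_bg = np.ones((n, 4))
    b_m = np.ones((n, M))
    bb = np.empty(4)
    new_bg = np.empty(4)
    new_m = np.empty(M)

    for t in range(T - 2, -1, -1):
        for i in range(n):
            zt1 = z[t + 1, i]
            for b in range(4):
                bb[b] = Ebg[t + 1, i, b] * b_bg[i, b]
            entry_flux = 0.0
            for br in range(nbr):
                entry_flux += entries[br] * Em[t + 1, i, br * L] * b_m[i, br * L]
            a_sum = 0.0
            for a in range(4):
                a_sum += alphas_bg[t, i, a]
            num[i] += a_sum * entry_flux / zt1
            bbinit = 0.0
            for b in range(4):
                bbinit += init[b] * bb[b]
            for a in range(4):
                acc = entry_flux
                for b in range(4):
                    acc += c * trans[a, b] * bb[b]
                new_bg[a] = acc / zt1
            for br in range(nbr):
                off = br * L
                for j in range(L - 1):
                    new_m[off + j] = Em[t + 1, i, off + j + 1] * b_m[i, off + j + 1] / zt1
                new_m[off + L - 1] = bbinit / zt1
            occ = 0.0
            for a in range(4):
                b_bg[i, a] = new_bg[a]
                occ += alphas_bg[t, i, a] * new_bg[a]
            den[i] += occ
            for k in range(M):
                b_m[i, k] = new_m[k]

    for i in range(n):
        start_flux = 0.0
        for br in range(nbr):
            start_flux += entries[br] * Em[0, i, br * L] * b_m[i, br * L]
        num[i] += start_flux / z[0, i]
    return num, den
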