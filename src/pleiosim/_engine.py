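"""Compiled Moran event loop.

One kernel implements both the production engine (fitness values cached per
individual, refreshed only at births and environment changes) and a naive
oracle engine (every phenotype and fitness recomputed from the genotypes at
every event).  Both paths consume the pseudo-random stream in exactly the
same order, so at a fixed seed they must produce bit-identical populations —
the naive path exists to prove the caching correct.

Random draws per event, in order: parent uniform (two in sexual mode),
recombination coins (sexual mode), mutation coins and effect draws, death
uniform.  The optimum trajectory is pre-drawn outside the kernel and enters
as one optimum per environmental epoch.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["moran_events"]


@njit(cache=True)
def _pheno(ci, ai, out):
    n_traits, n_a = ci.shape
    for t in range(n_traits):
        s = 0.0
        for j in range(n_a):
            s += ci[t, j] * ai[j]
        out[t] = s


@njit(cache=True)
def _fit(zi, opt, inv2v):
    d = 0.0
    for t in range(zi.shape[0]):
        e = zi[t] - opt[t]
        d += e * e
    return np.exp(-d * inv2v)


@njit(cache=True)
def _pick_parent(w, wsum, selection):
    n = w.shape[0]
    u = np.random.random()
    if (not selection) or wsum <= 0.0:
        k = int(u * n)
        if k >= n:
            k = n - 1
        return k
    target = u * wsum
    acc = 0.0
    for k in range(n):
        acc += w[k]
        if acc >= target:
            return k
    return n - 1


@njit(cache=True)
def moran_events(
    a,                # (N, n_a) float64, modified in place
    c,                # (N, n_traits, n_a) float64, modified in place
    opt_epochs,       # (n_epochs, n_traits): optimum per environmental epoch
    events_per_epoch, # int: events between environment changes
    n_events,         # int
    mu_a, mu_c, mut_sd,
    inv2v,            # 1 / (2 * selection_var)
    sexual,           # bool
    selection,        # bool
    seed,             # uint32-range int
    naive,            # bool: recompute all phenotypes/fitnesses every event
    snap_events,      # sorted int64 array: record population after this many events
    snap_a,           # (K, N, n_a) output
    snap_c,           # (K, N, n_traits, n_a) output
    snap_opt,         # (K, n_traits) output
    fit_events,       # sorted int64 array: record mean fitness after this many events
    fit_out,          # (F,) output
):
    np.random.seed(seed)
    N, n_a = a.shape
    n_traits = c.shape[1]
    n_epochs = opt_epochs.shape[0]

    z = np.empty((N, n_traits))
    w = np.empty(N)
    off_a = np.empty(n_a)
    off_c = np.empty((n_traits, n_a))
    off_z = np.empty(n_traits)

    epoch = 0
    opt = opt_epochs[0]
    for k in range(N):
        _pheno(c[k], a[k], z[k])
        w[k] = _fit(z[k], opt, inv2v)
    # The fitness total is re-summed from the cached values every event (in
    # index order) rather than updated in place: summation order then matches
    # the naive engine exactly, keeping the two paths bit-identical.
    wsum = 0.0
    for k in range(N):
        wsum += w[k]

    si = 0
    fi = 0
    # records scheduled at 0 events = initial state
    while si < snap_events.shape[0] and snap_events[si] == 0:
        snap_a[si] = a
        snap_c[si] = c
        snap_opt[si] = opt
        si += 1
    while fi < fit_events.shape[0] and fit_events[fi] == 0:
        fit_out[fi] = wsum / N
        fi += 1

    for ev in range(n_events):
        e = ev // events_per_epoch
        if e >= n_epochs:
            e = n_epochs - 1
        if e != epoch:
            epoch = e
            opt = opt_epochs[epoch]
            for k in range(N):
                w[k] = _fit(z[k], opt, inv2v)
        if naive:
            for k in range(N):
                _pheno(c[k], a[k], z[k])
                w[k] = _fit(z[k], opt, inv2v)
        wsum = 0.0
        for k in range(N):
            wsum += w[k]

        p1 = _pick_parent(w, wsum, selection)
        if sexual:
            p2 = _pick_parent(w, wsum, selection)
            for j in range(n_a):
                off_a[j] = a[p1, j] if np.random.random() < 0.5 else a[p2, j]
            for t in range(n_traits):
                for j in range(n_a):
                    off_c[t, j] = c[p1, t, j] if np.random.random() < 0.5 else c[p2, t, j]
        else:
            for j in range(n_a):
                off_a[j] = a[p1, j]
            for t in range(n_traits):
                for j in range(n_a):
                    off_c[t, j] = c[p1, t, j]

        for j in range(n_a):
            if np.random.random() < mu_a:
                off_a[j] += np.random.normal(0.0, mut_sd)
        for t in range(n_traits):
            for j in range(n_a):
                if np.random.random() < mu_c:
                    off_c[t, j] += np.random.normal(0.0, mut_sd)

        d = int(np.random.random() * N)
        if d >= N:
            d = N - 1

        _pheno(off_c, off_a, off_z)
        new_w = _fit(off_z, opt, inv2v)
        for j in range(n_a):
            a[d, j] = off_a[j]
        for t in range(n_traits):
            for j in range(n_a):
                c[d, t, j] = off_c[t, j]
            z[d, t] = off_z[t]
        w[d] = new_w

        done = ev + 1
        while si < snap_events.shape[0] and snap_events[si] == done:
            snap_a[si] = a
            snap_c[si] = c
            snap_opt[si] = opt
            si += 1
        while fi < fit_events.shape[0] and fit_events[fi] == done:
            s = 0.0
            for k in range(N):
                s += w[k]
            fit_out[fi] = s / N
            fi += 1
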