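"""Direct-method Gillespie kernel (numba-jitted, with a pure-Python twin).

The kernel simulates the continuous-time Markov chain defined by a
:class:`~chromem.model.ReactionNetwork`'s propensity convention: first-order
``coeff * n_sub`` and catalysed ``coeff * n_sub * n_cat / D_tot`` (optionally
a Hill saturation of the catalyst fraction).  It supports a hard time
horizon, a linear stop condition ``w . n <= c`` / ``w . n >= c`` (first-
passage sampling), state sampling on a fixed grid, and bounded event
logging.  Randomness comes from the legacy per-thread NumPy RNG seeded
explicitly, so identical seeds give identical event sequences.
"""

from __future__ import annotations

import numpy as np

# status codes
REACHED_TMAX = 0
STOPPED = 1
ABSORBED = 2


def _ssa_core(n0, t0, t_max, sub_idx, coeff, S, cat, hill_K, hill_h, dtot,
              stop_w, stop_c, stop_mode, ev_t, ev_r, seed):
    """Run one SSA realization without state sampling.  Returns (t_end,
    status, n_events, total_events); ``n0`` is modified in place to the final
    state and the event buffers are filled up to their capacity."""
    np.random.seed(seed)
    n = n0
    R = sub_idx.shape[0]
    a = np.empty(R)
    t = t0
    max_ev = ev_t.shape[0]
    n_ev = 0
    total = 0

    # stop condition may hold at the initial state
    if stop_mode != 0:
        val = 0.0
        for k in range(n.shape[0]):
            val += stop_w[k] * n[k]
        if (stop_mode == 1 and val <= stop_c) or (stop_mode == 2 and val >= stop_c):
            return t, STOPPED, 0, 0

    while True:
        a0 = 0.0
        for r in range(R):
            ar = coeff[r] * n[sub_idx[r]]
            if ar > 0.0:
                csum = 0.0
                has_cat = False
                for k in range(n.shape[0]):
                    if cat[r, k] != 0.0:
                        has_cat = True
                        csum += cat[r, k] * n[k]
                if has_cat:
                    frac = csum / dtot
                    if hill_h[r] > 0.0:
                        fh = frac ** hill_h[r]
                        denom = hill_K[r] ** hill_h[r] + fh
                        ar = ar * (fh / denom) if denom > 0.0 else 0.0
                    else:
                        ar = ar * frac
            a[r] = ar
            a0 += ar
        if a0 <= 0.0:
            return t, ABSORBED, n_ev, total
        t_next = t + np.random.exponential(1.0 / a0)
        if t_next > t_max:
            return t_max, REACHED_TMAX, n_ev, total
        # choose reaction
        u = np.random.random() * a0
        acc = 0.0
        rsel = R - 1
        for r in range(R):
            acc += a[r]
            if u < acc:
                rsel = r
                break
        for k in range(n.shape[0]):
            n[k] += S[rsel, k]
        t = t_next
        total += 1
        if n_ev < max_ev:
            ev_t[n_ev] = t
            ev_r[n_ev] = rsel
            n_ev += 1
        if stop_mode != 0:
            val = 0.0
            for k in range(n.shape[0]):
                val += stop_w[k] * n[k]
            if (stop_mode == 1 and val <= stop_c) or (stop_mode == 2 and val >= stop_c):
                return t, STOPPED, n_ev, total


def _ssa_core_sampling(n0, t0, t_max, sub_idx, coeff, S, cat, hill_K, hill_h,
                       dtot, stop_w, stop_c, stop_mode, sample_times, samples,
                       ev_t, ev_r, seed):
    """Same as :func:`_ssa_core` but also records the state at sample times."""
    np.random.seed(seed)
    n = n0
    R = sub_idx.shape[0]
    a = np.empty(R)
    t = t0
    si = 0
    n_samp = sample_times.shape[0]
    max_ev = ev_t.shape[0]
    n_ev = 0
    total = 0

    if stop_mode != 0:
        val = 0.0
        for k in range(n.shape[0]):
            val += stop_w[k] * n[k]
        if (stop_mode == 1 and val <= stop_c) or (stop_mode == 2 and val >= stop_c):
            return t, STOPPED, 0, 0, 0

    while True:
        a0 = 0.0
        for r in range(R):
            ar = coeff[r] * n[sub_idx[r]]
            if ar > 0.0:
                csum = 0.0
                has_cat = False
                for k in range(n.shape[0]):
                    if cat[r, k] != 0.0:
                        has_cat = True
                        csum += cat[r, k] * n[k]
                if has_cat:
                    frac = csum / dtot
                    if hill_h[r] > 0.0:
                        fh = frac ** hill_h[r]
                        denom = hill_K[r] ** hill_h[r] + fh
                        ar = ar * (fh / denom) if denom > 0.0 else 0.0
                    else:
                        ar = ar * frac
            a[r] = ar
            a0 += ar
        if a0 <= 0.0:
            while si < n_samp and sample_times[si] <= t_max:
                for k in range(n.shape[0]):
                    samples[si, k] = n[k]
                si += 1
            return t, ABSORBED, si, n_ev, total
        t_next = t + np.random.exponential(1.0 / a0)
        while si < n_samp and sample_times[si] < t_next and sample_times[si] <= t_max:
            for k in range(n.shape[0]):
                samples[si, k] = n[k]
            si += 1
        if t_next > t_max:
            return t_max, REACHED_TMAX, si, n_ev, total
        u = np.random.random() * a0
        acc = 0.0
        rsel = R - 1
        for r in range(R):
            acc += a[r]
            if u < acc:
                rsel = r
                break
        for k in range(n.shape[0]):
            n[k] += S[rsel, k]
        t = t_next
        total += 1
        if n_ev < max_ev:
            ev_t[n_ev] = t
            ev_r[n_ev] = rsel
            n_ev += 1
        if stop_mode != 0:
            val = 0.0
            for k in range(n.shape[0]):
                val += stop_w[k] * n[k]
            if (stop_mode == 1 and val <= stop_c) or (stop_mode == 2 and val >= stop_c):
                return t, STOPPED, si, n_ev, total


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    ssa_core = njit(cache=False)(_ssa_core)
    ssa_core_sampling = njit(cache=False)(_ssa_core_sampling)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    ssa_core = _ssa_core
    ssa_core_sampling = _ssa_core_sampling
    HAVE_NUMBA = False
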