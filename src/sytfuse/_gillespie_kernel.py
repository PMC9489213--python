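"""Numba kernel for the exact per-syt stochastic simulation.

The state of the system is an ``n_rows x n_ves`` matrix of per-syt codes
(0 = unbound, 1 = PI(4,5)P2 bound, 2 = Ca2+ bound, 3 = dual bound,
-1 = syt absent on this vesicle).  Each event draws four uniforms in a
fixed order -- waiting time, vesicle, syt-or-fusion row, reaction -- and
selection uses cumulative sums ("smallest index whose running sum reaches
r times the total").  With a time-varying stimulus, waiting times are
capped (default 0.8 ms): a longer draw advances time with no reaction and
refreshes the concentrations and all propensities.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# per-syt codes
UNBOUND, PIP2_ONLY, CA_ONLY, DUAL, ABSENT = 0, 1, 2, 3, -1


@njit(cache=False)
def _interp(t, xs, ys):
    """Linear interpolation with edge clamping (xs strictly increasing)."""
    if t <= xs[0]:
        return ys[0]
    if t >= xs[-1]:
        return ys[-1]
    i = np.searchsorted(xs, t)
    x0, x1 = xs[i - 1], xs[i]
    return ys[i - 1] + (ys[i] - ys[i - 1]) * (t - x0) / (x1 - x0)


@njit(cache=False)
def _syt_propensity(code, pip_free, ca_pow, pip2_conc,
                    alpha_c, beta_c, gamma_c, delta_c, A_c):
    """Total reaction propensity of one syt given its code and free slots."""
    if code == UNBOUND:
        return pip_free * gamma_c * pip2_conc + alpha_c * ca_pow
    elif code == PIP2_ONLY:
        return delta_c + alpha_c * ca_pow
    elif code == CA_ONLY:
        return beta_c + pip_free * gamma_c * pip2_conc
    elif code == DUAL:
        return A_c * delta_c + A_c * beta_c
    return 0.0


@njit(cache=False)
def _vesicle_propensity(cnt, j, n_classes, piptot, M_slots,
                        ca_pow, pip2_conc, alpha, beta, gamma, delta, A,
                        L_plus, f, dual_count):
    """Propensity of vesicle j from its per-class code counts (``cnt`` has
    one row per (class, code) pair) plus its fusion propensity."""
    pip_free = M_slots - piptot
    if pip_free < 0:
        pip_free = 0
    total = 0.0
    for p in range(n_classes):
        base = 4 * p
        total += cnt[base + UNBOUND, j] * (
            pip_free * gamma[p] * pip2_conc + alpha[p] * ca_pow)
        total += cnt[base + PIP2_ONLY, j] * (delta[p] + alpha[p] * ca_pow)
        total += cnt[base + CA_ONLY, j] * (
            beta[p] + pip_free * gamma[p] * pip2_conc)
        total += cnt[base + DUAL, j] * A[p] * (delta[p] + beta[p])
    return total + L_plus * f**dual_count


@njit(cache=False)
def gillespie_run(codes, cls_row, alpha, beta, gamma, delta, A,
                  ca_t, ca_v, pip2_t, pip2_v, time_varying,
                  M_slots, L_plus, f, ca_exponent,
                  t_end, cap_dt, seed,
                  census_times, census_out,
                  record_episodes, episode_out,
                  fusion_times, dual_at_fusion):
    """Simulate one batch of vesicles to ``t_end`` (or until all fused).

    Mutates ``codes`` in place and fills ``fusion_times`` (np.inf when the
    vesicle never fuses), ``dual_at_fusion``, the census count matrix
    (vesicles with 0..M_slots dual bindings among the unfused, one row per
    census time) and, optionally, completed dual-binding episode durations.
    Returns the number of recorded episodes.
    """
    np.random.seed(seed)
    n_rows, n_ves = codes.shape

    n_classes = alpha.shape[0]
    piptot = np.zeros(n_ves, dtype=np.int64)
    dual = np.zeros(n_ves, dtype=np.int64)
    fused = np.zeros(n_ves, dtype=np.bool_)
    cnt = np.zeros((4 * n_classes, n_ves), dtype=np.int64)
    for j in range(n_ves):
        for i in range(n_rows):
            c = codes[i, j]
            if c == ABSENT:
                continue
            cnt[4 * cls_row[i] + c, j] += 1
            if c == PIP2_ONLY or c == DUAL:
                piptot[j] += 1
            if c == DUAL:
                dual[j] += 1

    t = 0.0
    ca = _interp(0.0, ca_t, ca_v)
    pip2c = _interp(0.0, pip2_t, pip2_v)
    ca_pow = ca**ca_exponent

    Bsv = np.zeros(n_ves)
    for j in range(n_ves):
        Bsv[j] = _vesicle_propensity(cnt, j, n_classes, piptot[j],
                                     M_slots, ca_pow, pip2c,
                                     alpha, beta, gamma, delta, A,
                                     L_plus, f, dual[j])
    B0 = Bsv.sum()

    epi_start = np.full((n_rows, n_ves), -1.0)
    n_epi = 0
    max_epi = episode_out.shape[0]
    n_census = census_times.shape[0]
    ci = 0
    events_since_refresh = 0

    while True:
        if B0 <= 0.0 and not time_varying:
            break
        r1 = np.random.random()
        tau = np.log(1.0 / r1) / B0 if B0 > 0.0 else np.inf
        capped = time_varying and tau > cap_dt
        t_next = t + (cap_dt if capped else tau)
        if t_next > t_end:
            t_next = t_end
        # census snapshots strictly before the state changes at t_next
        while ci < n_census and census_times[ci] <= t_next:
            for j in range(n_ves):
                if not fused[j]:
                    census_out[ci, dual[j]] += 1
            ci += 1
        if t + tau > t_end and not capped:
            break
        t = t_next
        if t >= t_end:
            break
        if capped:
            # no reaction: refresh concentrations and all propensities
            ca = _interp(t, ca_t, ca_v)
            pip2c = _interp(t, pip2_t, pip2_v)
            ca_pow = ca**ca_exponent
            B0 = 0.0
            for j in range(n_ves):
                if fused[j]:
                    Bsv[j] = 0.0
                else:
                    Bsv[j] = _vesicle_propensity(
                        cnt, j, n_classes, piptot[j], M_slots,
                        ca_pow, pip2c, alpha, beta, gamma, delta, A,
                        L_plus, f, dual[j])
                B0 += Bsv[j]
            continue

        # select vesicle j: first index with cumulative sum >= r2 * B0
        r2 = np.random.random()
        target = r2 * B0
        acc = 0.0
        j = n_ves - 1
        for jj in range(n_ves):
            acc += Bsv[jj]
            if acc >= target:
                j = jj
                break

        pip_free = M_slots - piptot[j]
        if pip_free < 0:
            pip_free = 0

        # select row i (syt or the extra fusion row) within vesicle j
        r3 = np.random.random()
        target = r3 * Bsv[j]
        acc = 0.0
        row = n_rows  # fusion row by default
        for i in range(n_rows):
            c = codes[i, j]
            if c == ABSENT:
                continue
            p = cls_row[i]
            acc += _syt_propensity(c, pip_free, ca_pow, pip2c,
                                   alpha[p], beta[p], gamma[p],
                                   delta[p], A[p])
            if acc >= target:
                row = i
                break

        if row == n_rows:
            # fusion of vesicle j
            fusion_times[j] = t
            dual_at_fusion[j] = dual[j]
            fused[j] = True
            if record_episodes:
                for i in range(n_rows):
                    epi_start[i, j] = -1.0  # censored by fusion, discarded
            B0 -= Bsv[j]
            Bsv[j] = 0.0
            if B0 < 0.0:
                B0 = 0.0
            if time_varying:
                ca = _interp(t, ca_t, ca_v)
                pip2c = _interp(t, pip2_t, pip2_v)
                ca_pow = ca**ca_exponent
                B0 = 0.0
                for jj in range(n_ves):
                    if fused[jj]:
                        Bsv[jj] = 0.0
                    else:
                        Bsv[jj] = _vesicle_propensity(
                            cnt, jj, n_classes, piptot[jj], M_slots,
                            ca_pow, pip2c, alpha, beta, gamma, delta, A,
                            L_plus, f, dual[jj])
                    B0 += Bsv[jj]
            continue

        # select one of the four reactions: bind PIP2, bind Ca, unbind PIP2,
        # unbind Ca (in this order), conditioned on the syt's code
        c = codes[row, j]
        p = cls_row[row]
        b1 = pip_free * gamma[p] * pip2c if (c == UNBOUND or c == CA_ONLY) else 0.0
        b2 = alpha[p] * ca_pow if (c == UNBOUND or c == PIP2_ONLY) else 0.0
        b3 = 0.0
        if c == PIP2_ONLY:
            b3 = delta[p]
        elif c == DUAL:
            b3 = A[p] * delta[p]
        b4 = 0.0
        if c == CA_ONLY:
            b4 = beta[p]
        elif c == DUAL:
            b4 = A[p] * beta[p]
        btot = b1 + b2 + b3 + b4
        r4 = np.random.random()
        target = r4 * btot
        if target <= b1 and b1 > 0.0:
            h = 0
        elif target <= b1 + b2 and b2 > 0.0:
            h = 1
        elif target <= b1 + b2 + b3 and b3 > 0.0:
            h = 2
        else:
            h = 3

        old = c
        if h == 0:      # +PI(4,5)P2
            new = PIP2_ONLY if old == UNBOUND else DUAL
            piptot[j] += 1
        elif h == 1:    # +Ca2+
            new = CA_ONLY if old == UNBOUND else DUAL
        elif h == 2:    # -PI(4,5)P2
            new = UNBOUND if old == PIP2_ONLY else CA_ONLY
            piptot[j] -= 1
        else:           # -Ca2+
            new = UNBOUND if old == CA_ONLY else PIP2_ONLY
        codes[row, j] = new
        cnt[4 * p + old, j] -= 1
        cnt[4 * p + new, j] += 1
        if new == DUAL and old != DUAL:
            dual[j] += 1
            if record_episodes:
                epi_start[row, j] = t
        if old == DUAL and new != DUAL:
            dual[j] -= 1
            if record_episodes and epi_start[row, j] >= 0.0:
                if n_epi < max_epi:
                    episode_out[n_epi] = t - epi_start[row, j]
                    n_epi += 1
                epi_start[row, j] = -1.0

        if time_varying:
            # concentrations move with every step, so the whole propensity
            # matrix is refreshed at the new time
            ca = _interp(t, ca_t, ca_v)
            pip2c = _interp(t, pip2_t, pip2_v)
            ca_pow = ca**ca_exponent
            B0 = 0.0
            for jj in range(n_ves):
                if fused[jj]:
                    Bsv[jj] = 0.0
                else:
                    Bsv[jj] = _vesicle_propensity(
                        cnt, jj, n_classes, piptot[jj], M_slots,
                        ca_pow, pip2c, alpha, beta, gamma, delta, A,
                        L_plus, f, dual[jj])
                B0 += Bsv[jj]
        else:
            newB = _vesicle_propensity(cnt, j, n_classes, piptot[j],
                                       M_slots, ca_pow, pip2c,
                                       alpha, beta, gamma, delta, A,
                                       L_plus, f, dual[j])
            B0 += newB - Bsv[j]
            Bsv[j] = newB
            events_since_refresh += 1
            if events_since_refresh >= 16384:
                # periodic exact refresh against float drift
                events_since_refresh = 0
                B0 = 0.0
                for jj in range(n_ves):
                    B0 += Bsv[jj]

    # fill remaining census slots with the final state
    while ci < n_census:
        for j in range(n_ves):
            if not fused[j]:
                census_out[ci, dual[j]] += 1
        ci += 1
    return n_epi
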