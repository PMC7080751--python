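"""Numba-compiled event-driven Monte Carlo kernels.

Exact non-Markovian simulation: every cell carries a pending event time drawn
at its birth (a cycle-time draw for dividing cells, an exponential
stratification wait for differentiating basal cells, an exponential shedding
wait for suprabasal cells when shedding is enabled).  Events are processed in
time order by linear scan over the small per-clone cell arrays; there is no
time discretisation.

Cycle-time family codes: 0 exponential, 1 shifted gamma, 2 deterministic.
All times inside the kernels are in days; rates are per day.

Kernels seed numba's legacy ``np.random`` state at entry, so a call is fully
determined by its integer seed — this is what makes common random numbers
across likelihood grid points possible.
"""

import numpy as np
from numba import njit

EXPONENTIAL, SHIFTED_GAMMA, DETERMINISTIC = 0, 1, 2


@njit(cache=True)
def _cycle_draw(fam, mean_cc, shape, tmin):
    if fam == EXPONENTIAL:
        return np.random.exponential(mean_cc)
    if fam == DETERMINISTIC:
        return mean_cc
    return tmin + np.random.gamma(shape, (mean_cc - tmin) / shape)


@njit(cache=True)
def _residual_draw(fam, mean_cc, shape, tmin):
    """Stationary-renewal residual life: U times a length-biased cycle."""
    if fam == EXPONENTIAL:
        return np.random.exponential(mean_cc)
    u = np.random.random()
    if fam == DETERMINISTIC:
        return u * mean_cc
    scale = (mean_cc - tmin) / shape
    if np.random.random() < tmin / mean_cc:
        y = np.random.gamma(shape, scale)
    else:
        y = np.random.gamma(shape + 1.0, scale)
    return u * (tmin + y)


@njit(cache=True)
def _grow(a):
    b = np.empty(a.shape[0] * 2, dtype=a.dtype)
    b[: a.shape[0]] = a
    return b


@njit(cache=True)
def sp_clone_kernel(
    n_clones,
    rec_times,  # sorted, days
    fam,
    mean_cc,
    shape,
    tmin,
    r,
    gamma_day,
    mu_day,  # <=0 disables shedding: suprabasal cells accumulate
    rho,
    init_mode,  # 0 progenitor-initiated, 1 basal-representative
    seed,
):
    """Single-progenitor clones; returns (prog, diff, supra) count arrays.

    Division outcomes: PP w.p. r, PD w.p. 1-2r, DD w.p. r.  Differentiating
    basal cells stratify after Exp(1/gamma) waits; initial progenitors start
    at a stationary cycle phase.
    """
    np.random.seed(seed)
    T = rec_times.shape[0]
    prog = np.zeros((n_clones, T), np.int64)
    diff = np.zeros((n_clones, T), np.int64)
    supra = np.zeros((n_clones, T), np.int64)

    for c in range(n_clones):
        pt = np.empty(8, np.float64)  # pending division times of progenitors
        dt = np.empty(8, np.float64)  # pending stratification times
        st = np.empty(8, np.float64)  # pending shedding times (if mu > 0)
        n_p = 0
        n_d = 0
        n_s = 0
        n_s_acc = 0  # accumulated suprabasal count when shedding is off

        if init_mode == 0 or np.random.random() < rho:
            pt[0] = _residual_draw(fam, mean_cc, shape, tmin)
            n_p = 1
        else:
            dt[0] = np.random.exponential(1.0 / gamma_day)
            n_d = 1

        ri = 0
        while ri < T:
            # next event
            t_ev = 1.0e300
            which = -1
            idx = -1
            for i in range(n_p):
                if pt[i] < t_ev:
                    t_ev = pt[i]
                    which = 0
                    idx = i
            for i in range(n_d):
                if dt[i] < t_ev:
                    t_ev = dt[i]
                    which = 1
                    idx = i
            if mu_day > 0.0:
                for i in range(n_s):
                    if st[i] < t_ev:
                        t_ev = st[i]
                        which = 2
                        idx = i

            # record states at observation times preceding the event
            while ri < T and rec_times[ri] <= t_ev:
                prog[c, ri] = n_p
                diff[c, ri] = n_d
                supra[c, ri] = n_s if mu_day > 0.0 else n_s_acc
                ri += 1
            if ri >= T or which < 0:
                break

            if which == 0:  # division
                pt[idx] = pt[n_p - 1]
                n_p -= 1
                u = np.random.random()
                if u < r:  # PP
                    for _ in range(2):
                        if n_p >= pt.shape[0]:
                            pt = _grow(pt)
                        pt[n_p] = t_ev + _cycle_draw(fam, mean_cc, shape, tmin)
                        n_p += 1
                elif u < 1.0 - r:  # PD
                    if n_p >= pt.shape[0]:
                        pt = _grow(pt)
                    pt[n_p] = t_ev + _cycle_draw(fam, mean_cc, shape, tmin)
                    n_p += 1
                    if n_d >= dt.shape[0]:
                        dt = _grow(dt)
                    dt[n_d] = t_ev + np.random.exponential(1.0 / gamma_day)
                    n_d += 1
                else:  # DD
                    for _ in range(2):
                        if n_d >= dt.shape[0]:
                            dt = _grow(dt)
                        dt[n_d] = t_ev + np.random.exponential(1.0 / gamma_day)
                        n_d += 1
            elif which == 1:  # stratification
                dt[idx] = dt[n_d - 1]
                n_d -= 1
                if mu_day > 0.0:
                    if n_s >= st.shape[0]:
                        st = _grow(st)
                    st[n_s] = t_ev + np.random.exponential(1.0 / mu_day)
                    n_s += 1
                else:
                    n_s_acc += 1
            else:  # shedding
                st[idx] = st[n_s - 1]
                n_s -= 1

    return prog, diff, supra


@njit(cache=True)
def sp_dilution_kernel(
    init_intensity,  # (n_cells,) initial label per founding basal cell
    chase_times,  # sorted, days, including 0
    fam,
    mean_cc,
    shape,
    tmin,
    r,
    gamma_day,
    rho,
    seed,
    cap_per_time,
):
    """Label dilution in a homeostatic basal population of independent lineages.

    Each founding cell is a progenitor (stationary phase) w.p. rho, else a
    differentiating basal cell.  Every division halves the parent intensity
    into both daughters; differentiating cells keep their intensity until
    stratification removes them from the basal (observed) pool.

    Returns (intensities, counts): intensities[t, :counts[t]] are the label
    levels of all basal cells in existence at chase time t.  counts[t] == -1
    flags buffer overflow (caller re-runs with a larger cap).
    """
    np.random.seed(seed)
    T = chase_times.shape[0]
    n_cells = init_intensity.shape[0]
    out = np.zeros((T, cap_per_time), np.float64)
    counts = np.zeros(T, np.int64)

    for c in range(n_cells):
        pt = np.empty(8, np.float64)
        pI = np.empty(8, np.float64)
        dt = np.empty(8, np.float64)
        dI = np.empty(8, np.float64)
        n_p = 0
        n_d = 0
        I0 = init_intensity[c]
        if np.random.random() < rho:
            pt[0] = _residual_draw(fam, mean_cc, shape, tmin)
            pI[0] = I0
            n_p = 1
        else:
            dt[0] = np.random.exponential(1.0 / gamma_day)
            dI[0] = I0
            n_d = 1

        ri = 0
        while ri < T:
            t_ev = 1.0e300
            which = -1
            idx = -1
            for i in range(n_p):
                if pt[i] < t_ev:
                    t_ev = pt[i]
                    which = 0
                    idx = i
            for i in range(n_d):
                if dt[i] < t_ev:
                    t_ev = dt[i]
                    which = 1
                    idx = i

            while ri < T and chase_times[ri] <= t_ev:
                k = counts[ri]
                if k >= 0:
                    if k + n_p + n_d > cap_per_time:
                        counts[ri] = -1
                    else:
                        for i in range(n_p):
                            out[ri, k] = pI[i]
                            k += 1
                        for i in range(n_d):
                            out[ri, k] = dI[i]
                            k += 1
                        counts[ri] = k
                ri += 1
            if ri >= T or which < 0:
                break

            if which == 0:  # division halves the label into both daughters
                half = 0.5 * pI[idx]
                pt[idx] = pt[n_p - 1]
                pI[idx] = pI[n_p - 1]
                n_p -= 1
                u = np.random.random()
                if u < r:
                    for _ in range(2):
                        if n_p >= pt.shape[0]:
                            pt = _grow(pt)
                            pI = _grow(pI)
                        pt[n_p] = t_ev + _cycle_draw(fam, mean_cc, shape, tmin)
                        pI[n_p] = half
                        n_p += 1
                elif u < 1.0 - r:
                    if n_p >= pt.shape[0]:
                        pt = _grow(pt)
                        pI = _grow(pI)
                    pt[n_p] = t_ev + _cycle_draw(fam, mean_cc, shape, tmin)
                    pI[n_p] = half
                    n_p += 1
                    if n_d >= dt.shape[0]:
                        dt = _grow(dt)
                        dI = _grow(dI)
                    dt[n_d] = t_ev + np.random.exponential(1.0 / gamma_day)
                    dI[n_d] = half
                    n_d += 1
                else:
                    for _ in range(2):
                        if n_d >= dt.shape[0]:
                            dt = _grow(dt)
                            dI = _grow(dI)
                        dt[n_d] = t_ev + np.random.exponential(1.0 / gamma_day)
                        dI[n_d] = half
                        n_d += 1
            else:  # stratification: leaves the basal pool
                dt[idx] = dt[n_d - 1]
                dI[idx] = dI[n_d - 1]
                n_d -= 1

    return out, counts


# cell types in the hierarchy kernel: 0 stem, 1 progenitor, 2 differentiating
# daughter-pair codes: 0 SS, 1 SP, 2 SD, 3 PP, 4 PD, 5 DD
_PAIR_A = np.array([0, 0, 0, 1, 1, 2], np.int64)
_PAIR_B = np.array([0, 1, 2, 1, 2, 2], np.int64)


@njit(cache=True)
def hierarchy_clone_kernel(
    n_clones,
    rec_times,
    # per dividing type (stem=row 0, progenitor=row 1): cycle law + fate probs
    fams,  # (2,) int
    means,  # (2,) days
    shapes,  # (2,)
    tmins,  # (2,)
    fate_cum,  # (2, 6) cumulative probabilities over pair codes
    gamma_day,
    init_frac,  # (3,) probabilities of the initial cell being S/P/D
    seed,
):
    """Generic stem/progenitor/differentiating-cell clone simulator."""
    np.random.seed(seed)
    T = rec_times.shape[0]
    stem = np.zeros((n_clones, T), np.int64)
    prog = np.zeros((n_clones, T), np.int64)
    diff = np.zeros((n_clones, T), np.int64)
    supra = np.zeros((n_clones, T), np.int64)

    for c in range(n_clones):
        ev_t = np.empty(8, np.float64)
        ev_type = np.empty(8, np.int64)
        n = 0
        n_supra = 0

        u = np.random.random()
        if u < init_frac[0]:
            typ0 = 0
        elif u < init_frac[0] + init_frac[1]:
            typ0 = 1
        else:
            typ0 = 2
        if typ0 == 2:
            ev_t[0] = np.random.exponential(1.0 / gamma_day)
        else:
            ev_t[0] = _residual_draw(fams[typ0], means[typ0], shapes[typ0], tmins[typ0])
        ev_type[0] = typ0
        n = 1

        ri = 0
        while ri < T:
            t_ev = 1.0e300
            idx = -1
            for i in range(n):
                if ev_t[i] < t_ev:
                    t_ev = ev_t[i]
                    idx = i
            while ri < T and rec_times[ri] <= t_ev:
                ns = 0
                npg = 0
                nd = 0
                for i in range(n):
                    if ev_type[i] == 0:
                        ns += 1
                    elif ev_type[i] == 1:
                        npg += 1
                    else:
                        nd += 1
                stem[c, ri] = ns
                prog[c, ri] = npg
                diff[c, ri] = nd
                supra[c, ri] = n_supra
                ri += 1
            if ri >= T or idx < 0:
                break

            typ = ev_type[idx]
            ev_t[idx] = ev_t[n - 1]
            ev_type[idx] = ev_type[n - 1]
            n -= 1
            if typ == 2:  # stratification
                n_supra += 1
                continue
            u = np.random.random()
            pair = 5
            for k in range(6):
                if u < fate_cum[typ, k]:
                    pair = k
                    break
            for daughter in (_PAIR_A[pair], _PAIR_B[pair]):
                if n >= ev_t.shape[0]:
                    ev_t = _grow(ev_t)
                    new_types = np.empty(ev_type.shape[0] * 2, np.int64)
                    new_types[: ev_type.shape[0]] = ev_type
                    ev_type = new_types
                if daughter == 2:
                    ev_t[n] = t_ev + np.random.exponential(1.0 / gamma_day)
                else:
                    ev_t[n] = t_ev + _cycle_draw(
                        fams[daughter], means[daughter], shapes[daughter], tmins[daughter]
                    )
                ev_type[n] = daughter
                n += 1

    return stem, prog, diff, supra
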