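"""Numba kernels for the serial coalescent and finite-sites mutation overlay.

Everything in this module operates on plain numpy arrays so it can be JIT
compiled.  The public modules (:mod:`paleoabc.serialcoal`, :mod:`paleoabc.abc`)
wrap these kernels in the documented object API; the batched entry point
:func:`simulate_stats_batch` runs the *same* per-simulation code path as the
object API, so a reference table row and ``simulate_dataset`` with the same
seed pair are bit-identical.

Conventions
-----------
* Time runs backward in generations before present (BP).
* Deme sizes are female effective sizes; two lineages in a deme of constant
  size N coalesce after an expected N generations (haploid/mtDNA scale).
* ``N_d(t) = N_d(t0) * exp(-r_d * (t - t0))`` within a demographic segment,
  so r > 0 means forward-time growth.
* Bases are encoded A=0, G=1, C=2, T=3; transitions toggle the low bit
  (A<->G, C<->T), transversions jump to the other pair.

The simulator advances segment by segment between "breakpoints" (tip
activation times, demographic events, migration-window edges).  Within a
segment it uses one of two exact schemes:

* a general competing-risks scheme that inverts the integrated coalescent
  hazard per deme (handles exponential growth), redrawing candidates after
  every event, and
* a next-reaction scheme with accumulated hazards for migration-active
  segments with zero growth, where migration events are frequent and
  per-event cost must stay O(1).
"""

import numpy as np
from numba import njit

# sentinel returned in S[0] for a simulation that hit the time horizon
FAILED = -1


@njit(cache=True)
def seed(value):
    """Seed numba's internal RNG (separate from numpy's Python-level state)."""
    np.random.seed(value)


@njit(cache=True)
def sim_genealogy(sample_time, sample_deme, size0, growth0,
                  ev_time, ev_deme, ev_scale, ev_growth,
                  ev_src, ev_dst, ev_frac,
                  mig, mig_start, mig_stop, t_max):
    """Simulate one genealogy of serially sampled lineages.

    Returns ``(parent, node_time, node_deme, ok)``.  Tips are nodes
    ``0..n-1`` in input order; internal nodes are appended in coalescence
    order, so the root (when ``ok``) is the last node.  ``ok`` is False if
    the configuration failed to find a common ancestor before ``t_max``.
    """
    n = sample_time.shape[0]
    n_demes = size0.shape[0]
    ne = ev_time.shape[0]
    nn = 2 * n - 1

    parent = np.full(nn, -1, dtype=np.int64)
    node_time = np.zeros(nn, dtype=np.float64)
    node_deme = np.zeros(nn, dtype=np.int64)

    # merge breakpoints: tip activations, demographic events, and the
    # migration-window edges (rates must only change at segment boundaries)
    nbp = n + ne + 2
    bp_time = np.empty(nbp, dtype=np.float64)
    bp_kind = np.empty(nbp, dtype=np.int64)   # 0 = sample, 1 = event, 2 = no-op
    bp_idx = np.empty(nbp, dtype=np.int64)
    for i in range(n):
        bp_time[i] = sample_time[i]
        bp_kind[i] = 0
        bp_idx[i] = i
    for j in range(ne):
        bp_time[n + j] = ev_time[j]
        bp_kind[n + j] = 1
        bp_idx[n + j] = j
    bp_time[n + ne] = mig_start
    bp_kind[n + ne] = 2
    bp_idx[n + ne] = 0
    bp_time[n + ne + 1] = mig_stop
    bp_kind[n + ne + 1] = 2
    bp_idx[n + ne + 1] = 0
    order = np.argsort(bp_time, kind='mergesort')

    cur_size = size0.copy()
    cur_growth = growth0.copy()
    out_rate = np.zeros(n_demes, dtype=np.float64)
    for d in range(n_demes):
        s = 0.0
        for j in range(n_demes):
            if j != d:
                s += mig[d, j]
        out_rate[d] = s

    members = np.empty((n_demes, n), dtype=np.int64)
    k_by = np.zeros(n_demes, dtype=np.int64)
    coal_w = np.zeros(n_demes, dtype=np.float64)
    n_active = 0
    next_node = n
    t = 0.0
    ib = 0

    while True:
        if ib >= nbp and n_active <= 1:
            return parent, node_time, node_deme, True
        t_end = bp_time[order[ib]] if ib < nbp else t_max

        if t_end > t and n_active > 0:
            mig_on = (t >= mig_start) and (t < mig_stop)
            m_tot = 0.0
            if mig_on:
                for d in range(n_demes):
                    m_tot += k_by[d] * out_rate[d]
            all_zero = True
            for d in range(n_demes):
                if cur_growth[d] != 0.0:
                    all_zero = False

            if mig_on and m_tot > 0.0 and all_zero:
                # ---------- fast next-reaction path ----------
                lam = 0.0
                for d in range(n_demes):
                    kd = k_by[d]
                    coal_w[d] = kd * (kd - 1) / (2.0 * cur_size[d])
                    lam += coal_w[d]
                e_c = np.random.exponential(1.0)
                e_m = np.random.exponential(1.0)
                while True:
                    if n_active <= 1 and ib >= nbp:
                        return parent, node_time, node_deme, True
                    dt_c = e_c / lam if lam > 0.0 else np.inf
                    dt_m = e_m / m_tot if m_tot > 0.0 else np.inf
                    if dt_c < dt_m:
                        dt = dt_c
                        is_coal = True
                    else:
                        dt = dt_m
                        is_coal = False
                    if t + dt >= t_end:
                        t = t_end
                        break
                    t += dt
                    if t >= t_max:
                        return parent, node_time, node_deme, False
                    e_c -= lam * dt
                    e_m -= m_tot * dt
                    if is_coal:
                        u = np.random.random() * lam
                        acc = 0.0
                        dsel = -1
                        for d in range(n_demes):
                            acc += coal_w[d]
                            if u < acc:
                                dsel = d
                                break
                        if dsel < 0 or k_by[dsel] < 2:
                            for d in range(n_demes):
                                if k_by[d] >= 2:
                                    dsel = d
                                    break
                        kd = k_by[dsel]
                        i1 = np.random.randint(kd)
                        i2 = np.random.randint(kd - 1)
                        if i2 >= i1:
                            i2 += 1
                        node = next_node
                        next_node += 1
                        node_time[node] = t
                        node_deme[node] = dsel
                        parent[members[dsel, i1]] = node
                        parent[members[dsel, i2]] = node
                        members[dsel, i1] = node
                        members[dsel, i2] = members[dsel, kd - 1]
                        k_by[dsel] = kd - 1
                        n_active -= 1
                        lam -= coal_w[dsel]
                        coal_w[dsel] = (kd - 1) * (kd - 2) / (2.0 * cur_size[dsel])
                        lam += coal_w[dsel]
                        m_tot -= out_rate[dsel]
                        e_c = np.random.exponential(1.0)
                    else:
                        u = np.random.random() * m_tot
                        acc = 0.0
                        src = -1
                        for d in range(n_demes):
                            acc += k_by[d] * out_rate[d]
                            if u < acc:
                                src = d
                                break
                        if src < 0 or k_by[src] == 0:
                            for d in range(n_demes):
                                if k_by[d] > 0 and out_rate[d] > 0.0:
                                    src = d
                                    break
                        v = np.random.random() * out_rate[src]
                        acc = 0.0
                        dst = -1
                        for j in range(n_demes):
                            if j == src:
                                continue
                            acc += mig[src, j]
                            if v < acc:
                                dst = j
                                break
                        if dst < 0:
                            for j in range(n_demes):
                                if j != src and mig[src, j] > 0.0:
                                    dst = j
                        ks = k_by[src]
                        idx = np.random.randint(ks)
                        node = members[src, idx]
                        members[src, idx] = members[src, ks - 1]
                        k_by[src] = ks - 1
                        members[dst, k_by[dst]] = node
                        k_by[dst] += 1
                        lam -= coal_w[src] + coal_w[dst]
                        coal_w[src] = (ks - 1) * (ks - 2) / (2.0 * cur_size[src])
                        kd = k_by[dst]
                        coal_w[dst] = kd * (kd - 1) / (2.0 * cur_size[dst])
                        lam += coal_w[src] + coal_w[dst]
                        m_tot += out_rate[dst] - out_rate[src]
                        e_m = np.random.exponential(1.0)
            else:
                # ---------- general path (growth-aware candidate draws) ----------
                while True:
                    w_min = np.inf
                    is_coal = False
                    dsel = -1
                    if mig_on and m_tot > 0.0:
                        w_min = np.random.exponential(1.0 / m_tot)
                    for d in range(n_demes):
                        kd = k_by[d]
                        if kd >= 2:
                            c = kd * (kd - 1) / (2.0 * cur_size[d])
                            rho = cur_growth[d]
                            e = np.random.exponential(1.0)
                            if rho > 1e-14 or rho < -1e-14:
                                arg = 1.0 + rho * e / c
                                w = np.log(arg) / rho if arg > 0.0 else np.inf
                            else:
                                w = e / c
                            if w < w_min:
                                w_min = w
                                is_coal = True
                                dsel = d
                    if t + w_min >= t_end:
                        if not np.isfinite(w_min) and ib >= nbp:
                            # stranded lineages can never coalesce
                            return parent, node_time, node_deme, n_active <= 1
                        for d in range(n_demes):
                            g = cur_growth[d]
                            if g != 0.0:
                                cur_size[d] *= np.exp(-g * (t_end - t))
                        t = t_end
                        break
                    t_new = t + w_min
                    for d in range(n_demes):
                        g = cur_growth[d]
                        if g != 0.0:
                            cur_size[d] *= np.exp(-g * (t_new - t))
                    t = t_new
                    if t >= t_max:
                        return parent, node_time, node_deme, False
                    if is_coal:
                        kd = k_by[dsel]
                        i1 = np.random.randint(kd)
                        i2 = np.random.randint(kd - 1)
                        if i2 >= i1:
                            i2 += 1
                        node = next_node
                        next_node += 1
                        node_time[node] = t
                        node_deme[node] = dsel
                        parent[members[dsel, i1]] = node
                        parent[members[dsel, i2]] = node
                        members[dsel, i1] = node
                        members[dsel, i2] = members[dsel, kd - 1]
                        k_by[dsel] = kd - 1
                        n_active -= 1
                        if n_active <= 1 and ib >= nbp:
                            return parent, node_time, node_deme, True
                    else:
                        u = np.random.random() * m_tot
                        acc = 0.0
                        src = -1
                        dst = -1
                        for d in range(n_demes):
                            if k_by[d] == 0:
                                continue
                            for j in range(n_demes):
                                if j == d:
                                    continue
                                acc += k_by[d] * mig[d, j]
                                if u < acc:
                                    src = d
                                    dst = j
                                    break
                            if src >= 0:
                                break
                        if src < 0:
                            continue
                        ks = k_by[src]
                        idx = np.random.randint(ks)
                        node = members[src, idx]
                        members[src, idx] = members[src, ks - 1]
                        k_by[src] = ks - 1
                        members[dst, k_by[dst]] = node
                        k_by[dst] += 1
                        m_tot = 0.0
                        for d in range(n_demes):
                            m_tot += k_by[d] * out_rate[d]
        elif t_end > t:
            # no active lineages yet: jump ahead, keeping sizes current
            for d in range(n_demes):
                g = cur_growth[d]
                if g != 0.0:
                    cur_size[d] *= np.exp(-g * (t_end - t))
            t = t_end

        if ib >= nbp:
            # reached the horizon without coalescing
            return parent, node_time, node_deme, n_active <= 1

        # process the breakpoint at time t == t_end
        kb = bp_kind[order[ib]]
        ix = bp_idx[order[ib]]
        ib += 1
        if kb == 0:
            d = sample_deme[ix]
            members[d, k_by[d]] = ix
            k_by[d] += 1
            node_time[ix] = sample_time[ix]
            node_deme[ix] = d
            n_active += 1
        elif kb == 1:
            d = ev_deme[ix]
            if d >= 0:
                cur_size[d] *= ev_scale[ix]
                cur_growth[d] = ev_growth[ix]
            src = ev_src[ix]
            if src >= 0:
                dst = ev_dst[ix]
                frac = ev_frac[ix]
                i = k_by[src] - 1
                while i >= 0:
                    if frac >= 1.0 or np.random.random() < frac:
                        node = members[src, i]
                        members[src, i] = members[src, k_by[src] - 1]
                        k_by[src] -= 1
                        members[dst, k_by[dst]] = node
                        k_by[dst] += 1
                    i -= 1


@njit(cache=True)
def mutate_tree(parent, node_time, n_tips, locus_len, mu_site, alpha, kappa):
    """Drop K2P mutations with gamma site-rate heterogeneity on a genealogy.

    Returns ``(root_base, sites, tip_state)`` where ``sites`` are the
    positions (0-based, over the concatenated loci) that received at least
    one mutation and ``tip_state[k, i]`` is the base of tip ``i`` at
    ``sites[k]``.  Unlisted sites carry the root base in every tip.
    """
    nn = 2 * n_tips - 1
    nb = nn - 1  # branches (root has none)
    L = 0
    nl = locus_len.shape[0]
    for l in range(nl):
        L += locus_len[l]

    # cumulative branch lengths
    tot = 0.0
    cumb = np.empty(nb, dtype=np.float64)
    for i in range(nb):
        tot += node_time[parent[i]] - node_time[i]
        cumb[i] = tot

    # per-site intensities: mu_site[locus] * gamma(alpha, 1/alpha)
    cumw = np.empty(L, dtype=np.float64)
    wtot = 0.0
    pos = 0
    for l in range(nl):
        a = alpha[l]
        m = mu_site[l]
        for s in range(locus_len[l]):
            g = np.random.gamma(a, 1.0 / a) if a < 1e8 else 1.0
            wtot += m * g
            cumw[pos] = wtot
            pos += 1

    n_mut = np.random.poisson(wtot * tot) if wtot * tot > 0.0 else 0

    root_base = np.empty(L, dtype=np.uint8)
    for s in range(L):
        root_base[s] = np.random.randint(4)

    mut_site = np.empty(n_mut, dtype=np.int64)
    mut_branch = np.empty(n_mut, dtype=np.int64)
    for k in range(n_mut):
        u = np.random.random() * wtot
        mut_site[k] = np.searchsorted(cumw, u, side='right')
        v = np.random.random() * tot
        mut_branch[k] = np.searchsorted(cumb, v, side='right')

    morder = np.argsort(mut_site, kind='mergesort')

    # distinct mutated sites
    ns = 0
    prev = -1
    for k in range(n_mut):
        s = mut_site[morder[k]]
        if s != prev:
            ns += 1
            prev = s

    sites = np.empty(ns, dtype=np.int64)
    tip_state = np.empty((ns, n_tips), dtype=np.uint8)
    node_state = np.empty(nn, dtype=np.int64)

    p_ts = kappa / (kappa + 2.0)
    k0 = 0
    si = 0
    while k0 < n_mut:
        s = mut_site[morder[k0]]
        k1 = k0
        while k1 < n_mut and mut_site[morder[k1]] == s:
            k1 += 1
        sites[si] = s
        node_state[nn - 1] = root_base[s]
        for node in range(nn - 2, -1, -1):
            st = node_state[parent[node]]
            for k in range(k0, k1):
                if mut_branch[morder[k]] == node:
                    if np.random.random() < p_ts:
                        st ^= 1
                    else:
                        st ^= 2 + np.random.randint(2)
            node_state[node] = st
        for i in range(n_tips):
            tip_state[si, i] = node_state[i]
        si += 1
        k0 = k1

    return root_base, sites, tip_state


@njit(cache=True)
def layer_stats(sites_state, sites, tip_layer, n_layers, layer_n, locus_end):
    """Per-locus, per-layer segregating sites and mean pairwise difference.

    ``sites_state`` holds tip bases at the mutated sites only (positions in
    ``sites``); monomorphic sites contribute nothing to either statistic.
    ``locus_end`` gives the cumulative end position of each locus, so
    combined-alignment statistics are the sums over loci.
    Returns ``S`` and ``pd`` with shape (n_loci, n_layers).
    """
    ns = sites_state.shape[0]
    n = sites_state.shape[1]
    nl_loci = locus_end.shape[0]
    S = np.zeros((nl_loci, n_layers), dtype=np.int64)
    pd = np.zeros((nl_loci, n_layers), dtype=np.float64)
    counts = np.zeros((n_layers, 4), dtype=np.int64)
    for si in range(ns):
        loc = np.searchsorted(locus_end, sites[si], side='right')
        counts[:, :] = 0
        for i in range(n):
            counts[tip_layer[i], sites_state[si, i]] += 1
        for l in range(n_layers):
            distinct = 0
            ssq = 0
            for b in range(4):
                c = counts[l, b]
                if c > 0:
                    distinct += 1
                ssq += c * c
            if distinct >= 2:
                S[loc, l] += 1
            nl = layer_n[l]
            pd[loc, l] += (nl * nl - ssq) / 2.0
    for loc in range(nl_loci):
        for l in range(n_layers):
            nl = layer_n[l]
            if nl >= 2:
                pd[loc, l] /= nl * (nl - 1) / 2.0
            else:
                pd[loc, l] = 0.0
    return S, pd


@njit(cache=True)
def simulate_stats_batch(gseeds, mseeds,
                         sample_time, sample_deme, tip_layer, n_layers,
                         sizes, growths,
                         ev_time, ev_deme, ev_scale, ev_growth,
                         ev_src, ev_dst, ev_frac,
                         mig, mig_start, mig_stop,
                         locus_len, mu_site, alpha, kappa, t_max):
    """Run many (genealogy -> mutations -> layer stats) simulations.

    Per-simulation parameters are rows of the 2-D arrays; structural event
    fields (deme indices, move endpoints) are shared across simulations.
    A simulation that hits the time horizon is flagged with ``S[i,0]=FAILED``
    and must be redrawn by the caller.
    """
    nsim = gseeds.shape[0]
    layer_n = np.zeros(n_layers, dtype=np.int64)
    for i in range(sample_time.shape[0]):
        layer_n[tip_layer[i]] += 1
    n_loci = locus_len.shape[0]
    locus_end = np.cumsum(locus_len)

    S_out = np.zeros((nsim, n_loci, n_layers), dtype=np.int64)
    pd_out = np.zeros((nsim, n_loci, n_layers), dtype=np.float64)
    for r in range(nsim):
        np.random.seed(gseeds[r])
        parent, node_time, node_deme, ok = sim_genealogy(
            sample_time, sample_deme, sizes[r], growths[r],
            ev_time[r], ev_deme, ev_scale[r], ev_growth[r],
            ev_src, ev_dst, ev_frac[r],
            mig[r], mig_start[r], mig_stop[r], t_max)
        if not ok:
            S_out[r, 0, 0] = FAILED
            continue
        np.random.seed(mseeds[r])
        root_base, msites, tip_state = mutate_tree(
            parent, node_time, sample_time.shape[0],
            locus_len, mu_site[r], alpha, kappa)
        S, pd = layer_stats(tip_state, msites, tip_layer, n_layers, layer_n,
                            locus_end)
        for lc in range(n_loci):
            for l in range(n_layers):
                S_out[r, lc, l] = S[lc, l]
                pd_out[r, lc, l] = pd[lc, l]
    return S_out, pd_out
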