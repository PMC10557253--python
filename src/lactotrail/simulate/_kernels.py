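"""Numba kernels for the discrete-event Hudson coalescent.

Demographic events are compiled (see ``demography.py``) into parallel arrays
sorted by time in generations before present:

* kind 0 — size change: population ``a`` takes diploid size ``x``
* kind 1 — admixture pulse: each lineage currently in destination ``a`` moves
  to source ``b`` with probability ``x`` (backward-in-time semantics)
* kind 2 — split: all lineages in derived population ``a`` move to ancestral
  population ``b``; ``a`` no longer exists further back in time

Pair coalescence rate within a population of diploid size N is 1/(2N) per
generation. Error flags: 0 ok, 1 unreachable common ancestor (lineages left in
disconnected populations after the last event), 2 mutation buffer overflow.
"""

import numpy as np
from numba import njit

__all__ = ["branch_length_spectrum", "simulate_loci"]


@njit(cache=True, inline="always")
def _pick_lineage(pop_arr, k, target_pop, which):
    """Index of the ``which``-th (0-based) active lineage in ``target_pop``."""
    seen = -1
    for i in range(k):
        if pop_arr[i] == target_pop:
            seen += 1
            if seen == which:
                return i
    return -1


@njit(cache=True)
def branch_length_spectrum(n_by_pop, tally, ev_time, ev_kind, ev_a, ev_b, ev_x,
                           init_sizes, n_reps, seed):
    """Monte-Carlo expected branch lengths per derived-leaf configuration.

    Returns (B, total_mean, err) where B[i, j, k] is the mean branch length
    (generations) subtending exactly i/j/k sampled leaves of the up-to-three
    tally populations, and total_mean is the mean total tree length.
    """
    np.random.seed(seed)
    npop = len(n_by_pop)
    n = 0
    for p in range(npop):
        n += n_by_pop[p]
    t0 = n_by_pop[tally[0]] if tally[0] >= 0 else 0
    t1 = n_by_pop[tally[1]] if tally[1] >= 0 else 0
    t2 = n_by_pop[tally[2]] if tally[2] >= 0 else 0
    B = np.zeros((t0 + 1, t1 + 1, t2 + 1))
    total = 0.0
    nev = len(ev_time)

    pop_arr = np.empty(n, dtype=np.int64)
    d = np.zeros((n, 3), dtype=np.int64)
    sizes = np.empty(npop)

    for _rep in range(n_reps):
        k = 0
        for p in range(npop):
            for _ in range(n_by_pop[p]):
                pop_arr[k] = p
                d[k, 0] = 1 if p == tally[0] else 0
                d[k, 1] = 1 if p == tally[1] else 0
                d[k, 2] = 1 if p == tally[2] else 0
                k += 1
        for p in range(npop):
            sizes[p] = init_sizes[p]
        t = 0.0
        ei = 0
        while k > 1:
            t_next = ev_time[ei] if ei < nev else np.inf
            # total coalescence rate
            R = 0.0
            for p in range(npop):
                cnt = 0
                for i in range(k):
                    if pop_arr[i] == p:
                        cnt += 1
                if cnt > 1:
                    R += cnt * (cnt - 1) / 2.0 / (2.0 * sizes[p])
            if R > 0.0:
                w = np.random.exponential(1.0 / R)
            else:
                w = np.inf
            if t + w >= t_next and ei < nev:
                dt = t_next - t
                for i in range(k):
                    B[d[i, 0], d[i, 1], d[i, 2]] += dt
                total += dt * k
                t = t_next
                kind = ev_kind[ei]
                if kind == 0:
                    sizes[ev_a[ei]] = ev_x[ei]
                elif kind == 1:
                    for i in range(k):
                        if pop_arr[i] == ev_a[ei] and np.random.random() < ev_x[ei]:
                            pop_arr[i] = ev_b[ei]
                else:
                    for i in range(k):
                        if pop_arr[i] == ev_a[ei]:
                            pop_arr[i] = ev_b[ei]
                ei += 1
                continue
            if not np.isfinite(w):
                return B, total, 1  # stuck: no coalescence possible, no events left
            dt = w
            for i in range(k):
                B[d[i, 0], d[i, 1], d[i, 2]] += dt
            total += dt * k
            t += w
            # choose population proportional to its coalescence rate
            u = np.random.random() * R
            acc = 0.0
            cpop = -1
            ccnt = 0
            for p in range(npop):
                cnt = 0
                for i in range(k):
                    if pop_arr[i] == p:
                        cnt += 1
                if cnt > 1:
                    acc += cnt * (cnt - 1) / 2.0 / (2.0 * sizes[p])
                    if u < acc and cpop < 0:
                        cpop = p
                        ccnt = cnt
            if cpop < 0:
                cpop = npop - 1
                ccnt = 0
                for i in range(k):
                    if pop_arr[i] == cpop:
                        ccnt += 1
            w1 = np.random.randint(0, ccnt)
            w2 = np.random.randint(0, ccnt - 1)
            if w2 >= w1:
                w2 += 1
            i1 = _pick_lineage(pop_arr, k, cpop, w1)
            i2 = _pick_lineage(pop_arr, k, cpop, w2)
            d[i1, 0] += d[i2, 0]
            d[i1, 1] += d[i2, 1]
            d[i1, 2] += d[i2, 2]
            # swap-remove lineage i2
            k -= 1
            pop_arr[i2] = pop_arr[k]
            d[i2, 0] = d[k, 0]
            d[i2, 1] = d[k, 1]
            d[i2, 2] = d[k, 2]
    for a in range(t0 + 1):
        for b in range(t1 + 1):
            for c in range(t2 + 1):
                B[a, b, c] /= n_reps
    return B, total / n_reps, 0


@njit(cache=True)
def simulate_loci(n_by_pop, ev_time, ev_kind, ev_a, ev_b, ev_x, init_sizes,
                  n_loci, theta_locus, cap, seed):
    """Simulate independent non-recombining loci with infinite-sites mutation.

    theta_locus = mu * locus_len (per-generation mutation rate of the locus).
    Returns (site_masks, locus_counts, used, err). site_masks[m] is a uint64
    bitmask over the n <= 64 sampled haplotypes carrying the derived allele of
    mutation m; mutations of locus l occupy the slice given by locus_counts.
    """
    np.random.seed(seed)
    npop = len(n_by_pop)
    n = 0
    for p in range(npop):
        n += n_by_pop[p]
    site_masks = np.zeros(cap, dtype=np.uint64)
    locus_counts = np.zeros(n_loci, dtype=np.int64)
    used = 0
    nev = len(ev_time)

    pop_arr = np.empty(n, dtype=np.int64)
    mask = np.empty(n, dtype=np.uint64)
    birth = np.empty(n, dtype=np.float64)
    br_mask = np.empty(2 * n, dtype=np.uint64)
    br_len = np.empty(2 * n, dtype=np.float64)
    sizes = np.empty(npop)

    for locus in range(n_loci):
        k = 0
        for p in range(npop):
            for _ in range(n_by_pop[p]):
                pop_arr[k] = p
                mask[k] = np.uint64(1) << np.uint64(k)
                birth[k] = 0.0
                k += 1
        for p in range(npop):
            sizes[p] = init_sizes[p]
        t = 0.0
        ei = 0
        nbr = 0
        total_len = 0.0
        while k > 1:
            t_next = ev_time[ei] if ei < nev else np.inf
            R = 0.0
            for p in range(npop):
                cnt = 0
                for i in range(k):
                    if pop_arr[i] == p:
                        cnt += 1
                if cnt > 1:
                    R += cnt * (cnt - 1) / 2.0 / (2.0 * sizes[p])
            w = np.random.exponential(1.0 / R) if R > 0.0 else np.inf
            if t + w >= t_next and ei < nev:
                t = t_next
                kind = ev_kind[ei]
                if kind == 0:
                    sizes[ev_a[ei]] = ev_x[ei]
                elif kind == 1:
                    for i in range(k):
                        if pop_arr[i] == ev_a[ei] and np.random.random() < ev_x[ei]:
                            pop_arr[i] = ev_b[ei]
                else:
                    for i in range(k):
                        if pop_arr[i] == ev_a[ei]:
                            pop_arr[i] = ev_b[ei]
                ei += 1
                continue
            if not np.isfinite(w):
                return site_masks, locus_counts, used, 1
            t += w
            u = np.random.random() * R
            acc = 0.0
            cpop = -1
            ccnt = 0
            for p in range(npop):
                cnt = 0
                for i in range(k):
                    if pop_arr[i] == p:
                        cnt += 1
                if cnt > 1:
                    acc += cnt * (cnt - 1) / 2.0 / (2.0 * sizes[p])
                    if u < acc and cpop < 0:
                        cpop = p
                        ccnt = cnt
            if cpop < 0:
                cpop = npop - 1
                ccnt = 0
                for i in range(k):
                    if pop_arr[i] == cpop:
                        ccnt += 1
            w1 = np.random.randint(0, ccnt)
            w2 = np.random.randint(0, ccnt - 1)
            if w2 >= w1:
                w2 += 1
            i1 = _pick_lineage(pop_arr, k, cpop, w1)
            i2 = _pick_lineage(pop_arr, k, cpop, w2)
            # record the two child branches
            br_mask[nbr] = mask[i1]
            br_len[nbr] = t - birth[i1]
            total_len += br_len[nbr]
            nbr += 1
            br_mask[nbr] = mask[i2]
            br_len[nbr] = t - birth[i2]
            total_len += br_len[nbr]
            nbr += 1
            mask[i1] = mask[i1] | mask[i2]
            birth[i1] = t
            k -= 1
            pop_arr[i2] = pop_arr[k]
            mask[i2] = mask[k]
            birth[i2] = birth[k]
        n_mut = np.random.poisson(theta_locus * total_len)
        if used + n_mut > cap:
            return site_masks, locus_counts, used, 2
        for _m in range(n_mut):
            r = np.random.random() * total_len
            acc = 0.0
            chosen = nbr - 1
            for bi in range(nbr):
                acc += br_len[bi]
                if r < acc:
                    chosen = bi
                    break
            site_masks[used] = br_mask[chosen]
            used += 1
        locus_counts[locus] = n_mut
    return site_masks, locus_counts, used, 0
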