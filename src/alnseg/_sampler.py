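"""Numba inner loop of the change-point sampler.

The chain state is a sorted array of active boundaries (always a
superset of the fixed ones) plus per-class Dirichlet hyperparameters
``alpha`` and mixture weights ``pi``.  Segment multinomial parameters
are integrated out analytically (Dirichlet-multinomial marginal), and
segment class labels are integrated out during boundary moves and then
re-instantiated exactly by Gibbs — a partially collapsed scheme that
leaves the joint posterior invariant.

Per sweep:
  1. Metropolis toggle (birth/death) proposals on randomly chosen
     eligible boundaries under a Bernoulli(rho) inclusion prior;
  2. +/-1 shift proposals on randomly chosen free boundaries;
  3. exact Gibbs draw of every segment label given pi, alpha;
  4. conjugate Gibbs update of pi (symmetric Dirichlet(1) prior);
  5. componentwise random-walk Metropolis on log(alpha) with a
     Gamma(shape, scale) prior.

Fixed boundaries are never proposed for deletion or shift.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _bisect_left(arr, hi, x):
    lo = 0
    while lo < hi:
        mid = (lo + hi) // 2
        if arr[mid] < x:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _dm_logmarg(cum, i, j, alpha_c):
    """log Dirichlet-multinomial marginal of segment [i, j)."""
    A = cum.shape[1]
    S = 0.0
    acc = 0.0
    for a in range(A):
        aa = alpha_c[a]
        S += aa
        na = cum[j, a] - cum[i, a]
        if na > 0:
            acc += math.lgamma(aa + na) - math.lgamma(aa)
    N = j - i
    acc += math.lgamma(S) - math.lgamma(S + N)
    return acc


@njit(cache=True)
def _seg_collapsed(cum, i, j, alpha, logpi):
    """log sum_c pi_c * DM(segment | alpha_c): segment score with the
    class label integrated out."""
    K = alpha.shape[0]
    m = -1.0e308
    vals = np.empty(K)
    for c in range(K):
        v = logpi[c] + _dm_logmarg(cum, i, j, alpha[c])
        vals[c] = v
        if v > m:
            m = v
    s = 0.0
    for c in range(K):
        s += math.exp(vals[c] - m)
    return m + math.log(s)


@njit(cache=True)
def run_chain(
    cum,
    n,
    fixed,
    rho,
    alpha,
    pi,
    iterations,
    proposals,
    shift_proposals,
    sample_alpha,
    sample_pi,
    prior_shape,
    prior_scale,
    rw_step,
    seed,
    thin,
    n_states,
    bnd_cap,
    loglik,
    k_free,
    n_seg,
    pi_tr,
    alpha_tr,
    freq_tr,
    state_labels,
    state_nb,
    state_bnd,
    state_iters,
):
    """Run the sampler; fills the preallocated output arrays.

    Returns (n_stored, overflow): number of stored states and whether the
    per-state boundary buffer capacity ``bnd_cap`` was exceeded (the
    caller should retry with a larger cap; the chain itself is
    unaffected by the buffer).
    """
    np.random.seed(seed)
    K = alpha.shape[0]
    A = cum.shape[1]
    nf = fixed.shape[0]

    bnd = np.empty(n + 1, dtype=np.int64)
    nb = nf
    for f in range(nf):
        bnd[f] = fixed[f]
    is_fixed = np.zeros(n + 1, dtype=np.uint8)
    for f in range(nf):
        is_fixed[fixed[f]] = 1

    logpi = np.log(pi)
    log_rho = math.log(rho)
    log_1mrho = math.log(1.0 - rho)

    seg_scores = np.empty(K)
    seg_dm = np.empty(K)
    class_counts = np.empty((K, A))
    class_nseg = np.empty(K, dtype=np.int64)
    alpha_sum = np.empty(K)
    for c in range(K):
        s = 0.0
        for a in range(A):
            s += alpha[c, a]
        alpha_sum[c] = s

    labels = np.empty(n + 1, dtype=np.int64)
    seg_start = np.empty(n + 1, dtype=np.int64)
    seg_end = np.empty(n + 1, dtype=np.int64)

    n_stored = 0
    overflow = False

    for it in range(iterations):
        # --- 1. boundary toggles (collapsed over labels) ---
        if n > 1:
            for _ in range(proposals):
                b = 1 + int(np.random.random() * (n - 1))
                if b >= n or is_fixed[b] == 1:
                    continue
                idx = _bisect_left(bnd, nb, b)
                present = idx < nb and bnd[idx] == b
                if present:
                    left = bnd[idx - 1] if idx > 0 else 0
                    right = bnd[idx + 1] if idx + 1 < nb else n
                    dlog = (
                        _seg_collapsed(cum, left, right, alpha, logpi)
                        - _seg_collapsed(cum, left, b, alpha, logpi)
                        - _seg_collapsed(cum, b, right, alpha, logpi)
                        + log_1mrho
                        - log_rho
                    )
                    if math.log(np.random.random()) < dlog:
                        for t in range(idx, nb - 1):
                            bnd[t] = bnd[t + 1]
                        nb -= 1
                else:
                    left = bnd[idx - 1] if idx > 0 else 0
                    right = bnd[idx] if idx < nb else n
                    dlog = (
                        _seg_collapsed(cum, left, b, alpha, logpi)
                        + _seg_collapsed(cum, b, right, alpha, logpi)
                        - _seg_collapsed(cum, left, right, alpha, logpi)
                        + log_rho
                        - log_1mrho
                    )
                    if math.log(np.random.random()) < dlog:
                        for t in range(nb, idx, -1):
                            bnd[t] = bnd[t - 1]
                        bnd[idx] = b
                        nb += 1

            # --- 2. shift moves on free boundaries ---
            for _ in range(shift_proposals):
                if nb == 0:
                    break
                r = int(np.random.random() * nb)
                if r >= nb:
                    continue
                b = bnd[r]
                if is_fixed[b] == 1:
                    continue
                d = 1 if np.random.random() < 0.5 else -1
                b2 = b + d
                if b2 < 1 or b2 >= n or is_fixed[b2] == 1:
                    continue
                if d == 1 and r + 1 < nb and bnd[r + 1] == b2:
                    continue
                if d == -1 and r > 0 and bnd[r - 1] == b2:
                    continue
                left = bnd[r - 1] if r > 0 else 0
                right = bnd[r + 1] if r + 1 < nb else n
                dlog = (
                    _seg_collapsed(cum, left, b2, alpha, logpi)
                    + _seg_collapsed(cum, b2, right, alpha, logpi)
                    - _seg_collapsed(cum, left, b, alpha, logpi)
                    - _seg_collapsed(cum, b, right, alpha, logpi)
                )
                if math.log(np.random.random()) < dlog:
                    bnd[r] = b2

        # --- 3. Gibbs labels ---
        ns = nb + 1
        for c in range(K):
            class_nseg[c] = 0
            for a in range(A):
                class_counts[c, a] = 0.0
        ll = 0.0
        for s in range(ns):
            i = bnd[s - 1] if s > 0 else 0
            j = bnd[s] if s < nb else n
            seg_start[s] = i
            seg_end[s] = j
            m = -1.0e308
            for c in range(K):
                dm = _dm_logmarg(cum, i, j, alpha[c])
                seg_dm[c] = dm
                v = logpi[c] + dm
                seg_scores[c] = v
                if v > m:
                    m = v
            tot = 0.0
            for c in range(K):
                seg_scores[c] = math.exp(seg_scores[c] - m)
                tot += seg_scores[c]
            u = np.random.random() * tot
            acc = 0.0
            chosen = K - 1
            for c in range(K):
                acc += seg_scores[c]
                if u < acc:
                    chosen = c
                    break
            labels[s] = chosen
            ll += seg_dm[chosen]
            class_nseg[chosen] += 1
            for a in range(A):
                class_counts[chosen, a] += cum[j, a] - cum[i, a]

        # --- 4. conjugate Gibbs on pi ---
        if sample_pi:
            tot = 0.0
            for c in range(K):
                g = np.random.gamma(1.0 + class_nseg[c], 1.0)
                pi[c] = g
                tot += g
            for c in range(K):
                pi[c] /= tot
                logpi[c] = math.log(pi[c])

        # --- 5. random-walk MH on log(alpha) ---
        if sample_alpha:
            for c in range(K):
                for a in range(A):
                    old = alpha[c, a]
                    prop = old * math.exp(np.random.normal(0.0, rw_step))
                    s_old = alpha_sum[c]
                    s_new = s_old - old + prop
                    dll = 0.0
                    for s in range(ns):
                        if labels[s] != c:
                            continue
                        i = seg_start[s]
                        j = seg_end[s]
                        na = cum[j, a] - cum[i, a]
                        N = j - i
                        if na > 0:
                            dll += (
                                math.lgamma(prop + na)
                                - math.lgamma(prop)
                                - math.lgamma(old + na)
                                + math.lgamma(old)
                            )
                        dll += (
                            math.lgamma(s_new)
                            - math.lgamma(s_new + N)
                            - math.lgamma(s_old)
                            + math.lgamma(s_old + N)
                        )
                    dlog = (
                        dll
                        + prior_shape * (math.log(prop) - math.log(old))
                        - (prop - old) / prior_scale
                    )
                    if math.log(np.random.random()) < dlog:
                        alpha[c, a] = prop
                        alpha_sum[c] = s_new
            # keep recorded log-likelihood consistent with updated alpha
            ll = 0.0
            for s in range(ns):
                ll += _dm_logmarg(cum, seg_start[s], seg_end[s], alpha[labels[s]])

        # --- record ---
        loglik[it] = ll
        k_free[it] = nb - nf
        n_seg[it] = ns
        for c in range(K):
            pi_tr[it, c] = pi[c]
            tot = 0.0
            for a in range(A):
                alpha_tr[it, c, a] = alpha[c, a]
                tot += class_counts[c, a]
            if class_nseg[c] > 0:
                for a in range(A):
                    freq_tr[it, c, a] = class_counts[c, a] / tot
            else:
                for a in range(A):
                    freq_tr[it, c, a] = alpha[c, a] / alpha_sum[c]

        if it % thin == 0 and n_stored < n_states:
            st = n_stored
            for s in range(ns):
                for p in range(seg_start[s], seg_end[s]):
                    state_labels[st, p] = labels[s]
            if nb <= bnd_cap:
                state_nb[st] = nb
                for t in range(nb):
                    state_bnd[st, t] = bnd[t]
            else:
                state_nb[st] = -1
                overflow = True
            state_iters[st] = it
            n_stored += 1

    return n_stored, overflow
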