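"""Compiled kernels for candidate sampling, split search and tree growth.

All randomness inside these kernels flows through Numba's NumPy-compatible
global RNG state, seeded explicitly with :func:`seed_engine` before each
call sequence.  The Python-level API seeds the engine from an injected
``numpy.random.Generator``, so every forest is reproducible given a seed
and the compiled path is the same one exercised by the public sampling
functions.
"""

from __future__ import annotations

import numba as nb
import numpy as np

# variant codes used by grow_tree
RSF = 0
VARPROB = 1
SPLITWEIGHTS = 2
BLOCKVARSEL = 3
RANDOMBLOCK = 4
BLOCKFOREST = 5

VARIANT_CODES = {
    "rsf": RSF,
    "varprob": VARPROB,
    "splitweights": SPLITWEIGHTS,
    "blockvarsel": BLOCKVARSEL,
    "randomblock": RANDOMBLOCK,
    "blockforest": BLOCKFOREST,
}


@nb.njit(cache=True)
def seed_engine(seed):
    np.random.seed(seed)


# ---------------------------------------------------------------------------
# candidate sampling
# ---------------------------------------------------------------------------


@nb.njit(cache=True)
def sample_ids(p, k, cand, pos):
    """Draw k distinct ints from 0..p-1 into cand[pos:pos+k] (partial
    Fisher-Yates); returns the new fill position."""
    buf = np.arange(p)
    for i in range(k):
        j = i + np.random.randint(0, p - i)
        t = buf[i]
        buf[i] = buf[j]
        buf[j] = t
        cand[pos + i] = buf[i]
    return pos + k


@nb.njit(cache=True)
def sample_block(block_cols, off, pm, k, cand, pos):
    """Draw k distinct columns of one block (cols block_cols[off:off+pm])."""
    buf = np.arange(pm)
    for i in range(k):
        j = i + np.random.randint(0, pm - i)
        t = buf[i]
        buf[i] = buf[j]
        buf[j] = t
        cand[pos + i] = block_cols[off + buf[i]]
    return pos + k


@nb.njit(cache=True)
def sample_varprob(cum_prob, k, cand):
    """Sequential categorical draws over all variables, rejecting duplicates.

    cum_prob is the cumulative per-variable selection probability.  After
    50*p consecutive duplicate draws the remaining slots are filled by
    weighted sampling without replacement (exponential-race keys), which
    bounds the running time under extreme probability vectors.  Returns the
    number of distinct variables obtained (can be < k if fewer than k
    variables have positive probability).
    """
    p = cum_prob.shape[0]
    total = cum_prob[p - 1]
    seen = np.zeros(p, np.bool_)
    cnt = 0
    fails = 0
    limit = 50 * p
    while cnt < k and total > 0.0:
        u = np.random.random() * total
        v = np.searchsorted(cum_prob, u, side="right")
        if v >= p:
            v = p - 1
        if seen[v]:
            fails += 1
            if fails >= limit:
                break
        else:
            seen[v] = True
            cand[cnt] = v
            cnt += 1
            fails = 0
    if cnt < k:
        keys = np.empty(p)
        for v in range(p):
            prev = cum_prob[v - 1] if v > 0 else 0.0
            pr = cum_prob[v] - prev
            if seen[v] or pr <= 0.0:
                keys[v] = -np.inf
            else:
                keys[v] = np.log(np.random.random()) / pr
        while cnt < k:
            best = -1
            bk = -np.inf
            for v in range(p):
                if keys[v] > bk:
                    bk = keys[v]
                    best = v
            if best < 0:
                break
            cand[cnt] = best
            cnt += 1
            keys[best] = -np.inf
    return cnt


@nb.njit(cache=True)
def select_randomblock(cum_b):
    """One categorical draw over blocks with cumulative probabilities cum_b."""
    M = cum_b.shape[0]
    u = np.random.random() * cum_b[M - 1]
    m = np.searchsorted(cum_b, u, side="right")
    if m >= M:
        m = M - 1
    return m


@nb.njit(cache=True)
def select_blocks_half(M, selected):
    """Include each block independently with probability 0.5; redraw if the
    subset comes up empty.  Writes into ``selected`` and returns the number
    of attempts (1 = no empty draw occurred)."""
    attempts = 0
    while True:
        attempts += 1
        nsel = 0
        for m in range(M):
            if np.random.random() < 0.5:
                selected[m] = True
                nsel += 1
            else:
                selected[m] = False
        if nsel > 0:
            return attempts


# ---------------------------------------------------------------------------
# split criterion
# ---------------------------------------------------------------------------


@nb.njit(cache=True)
def logrank_pass(t_s, s_s, left):
    """Squared standardized log-rank statistic (O-E)^2 / V for a node sorted
    by time, split into left (left[i] True) and right children.

    Returns -1.0 when the statistic is inadmissible (V = 0).
    """
    ns = t_s.shape[0]
    nk = ns
    nl = 0
    for i in range(ns):
        if left[i]:
            nl += 1
    O = 0.0
    E = 0.0
    V = 0.0
    i = 0
    while i < ns:
        tcur = t_s[i]
        d = 0
        dL = 0
        g = 0
        gL = 0
        while i < ns and t_s[i] == tcur:
            if s_s[i] == 1:
                d += 1
                if left[i]:
                    dL += 1
            g += 1
            if left[i]:
                gL += 1
            i += 1
        if d > 0:
            r = nl / nk
            O += dL
            E += d * r
            den = nk - 1 if nk > 1 else 1
            V += d * r * (1.0 - r) * (nk - d) / den
        nk -= g
        nl -= gL
    if V <= 0.0:
        return -1.0
    return (O - E) * (O - E) / V


@nb.njit(cache=True)
def best_split(X, orows, t_s, s_s, cand, wts, ncand):
    """Evaluate one random split point per candidate and return the proposal
    with the highest weighted criterion.

    ``orows`` are the node's row ids sorted by time, aligned with ``t_s``
    and ``s_s``.  Returns (candidate index or -1, threshold, raw criterion,
    weighted criterion).  Ties keep the first-encountered proposal.
    """
    ns = orows.shape[0]
    best_j = -1
    best_thr = 0.0
    best_raw = -1.0
    best_w = -1.0
    left = np.empty(ns, np.bool_)
    for j in range(ncand):
        v = cand[j]
        mn = X[orows[0], v]
        mx = mn
        for i in range(1, ns):
            val = X[orows[i], v]
            if val < mn:
                mn = val
            elif val > mx:
                mx = val
        if mx <= mn:
            continue
        thr = mn + np.random.random() * (mx - mn)
        if thr >= mx:
            continue
        nl = 0
        for i in range(ns):
            l = X[orows[i], v] <= thr
            left[i] = l
            if l:
                nl += 1
        if nl == 0 or nl == ns:
            continue
        raw = logrank_pass(t_s, s_s, left)
        if raw < 0.0:
            continue
        wcrit = raw * wts[j]
        if wcrit > best_w:
            best_w = wcrit
            best_j = j
            best_thr = thr
            best_raw = raw
    return best_j, best_thr, best_raw, best_w


@nb.njit(cache=True)
def leaf_chf(t_s, s_s, grid, out_row):
    """Nelson-Aalen cumulative hazard of one node, evaluated on the forest's
    event-time grid.  t_s/s_s are the node's times/statuses sorted by time."""
    ns = t_s.shape[0]
    G = grid.shape[0]
    nk = ns
    i = 0
    H = 0.0
    for g in range(G):
        tg = grid[g]
        while i < ns and t_s[i] <= tg:
            tcur = t_s[i]
            d = 0
            c = 0
            while i < ns and t_s[i] == tcur:
                if s_s[i] == 1:
                    d += 1
                c += 1
                i += 1
            if d > 0:
                H += d / nk
            nk -= c
        out_row[g] = H


# ---------------------------------------------------------------------------
# tree growth
# ---------------------------------------------------------------------------


@nb.njit(cache=True)
def grow_tree_kernel(
    X,
    time,
    status,
    grid,
    inbag,
    variant,
    mtry_rsf,
    total_k,
    kms,
    block_cols,
    block_off,
    block_of_var,
    var_cum_prob,
    weights,
    use_weights,
    cum_b,
    mandatory,
    min_node_size,
):
    """Grow one survival tree by recursive partitioning (iterative stack).

    Returns (feature, threshold, left, right, leaf_slot, leaf_chf_matrix).
    Internal nodes have feature >= 0; terminal nodes have leaf_slot >= 0
    indexing rows of the leaf CHF matrix.  A node becomes terminal when its
    size is <= min_node_size, it contains no events, or no admissible split
    exists among the candidates.
    """
    n_in = inbag.shape[0]
    p = X.shape[1]
    G = grid.shape[0]
    M = kms.shape[0]
    max_nodes = 2 * n_in + 1

    feature = np.full(max_nodes, -1, np.int64)
    thresh = np.zeros(max_nodes)
    left_c = np.full(max_nodes, -1, np.int64)
    right_c = np.full(max_nodes, -1, np.int64)
    leaf_slot = np.full(max_nodes, -1, np.int64)
    chf = np.zeros((n_in, G))

    rows = inbag.copy()
    st_node = np.empty(max_nodes, np.int64)
    st_start = np.empty(max_nodes, np.int64)
    st_end = np.empty(max_nodes, np.int64)
    st_node[0] = 0
    st_start[0] = 0
    st_end[0] = n_in
    top = 1
    n_nodes = 1
    n_leaves = 0

    cand = np.empty(p, np.int64)
    wts = np.empty(p)
    selected = np.empty(M, np.bool_)
    tmp = np.empty(n_in, np.int64)

    while top > 0:
        top -= 1
        node = st_node[top]
        start = st_start[top]
        end = st_end[top]
        ns = end - start

        tvals = np.empty(ns)
        for i in range(ns):
            tvals[i] = time[rows[start + i]]
        order = np.argsort(tvals, kind="mergesort")
        orows = np.empty(ns, np.int64)
        t_s = np.empty(ns)
        s_s = np.empty(ns, np.int8)
        nev = 0
        for i in range(ns):
            r = rows[start + order[i]]
            orows[i] = r
            t_s[i] = tvals[order[i]]
            s_s[i] = status[r]
            if status[r] == 1:
                nev += 1

        split_done = False
        if ns > min_node_size and nev > 0:
            ncand = 0
            if variant == RSF:
                k = mtry_rsf if mtry_rsf < p else p
                ncand = sample_ids(p, k, cand, 0)
            elif variant == VARPROB:
                k = total_k if total_k < p else p
                ncand = sample_varprob(var_cum_prob, k, cand)
            elif variant == SPLITWEIGHTS:
                k = total_k if total_k < p else p
                ncand = sample_ids(p, k, cand, 0)
            elif variant == BLOCKVARSEL:
                pos = 0
                for m in range(M):
                    pos = sample_block(
                        block_cols,
                        block_off[m],
                        block_off[m + 1] - block_off[m],
                        kms[m],
                        cand,
                        pos,
                    )
                ncand = pos
            elif variant == RANDOMBLOCK:
                m = select_randomblock(cum_b)
                ncand = sample_block(
                    block_cols,
                    block_off[m],
                    block_off[m + 1] - block_off[m],
                    kms[m],
                    cand,
                    0,
                )
            else:  # BLOCKFOREST
                select_blocks_half(M, selected)
                pos = 0
                for m in range(M):
                    if selected[m]:
                        pos = sample_block(
                            block_cols,
                            block_off[m],
                            block_off[m + 1] - block_off[m],
                            kms[m],
                            cand,
                            pos,
                        )
                ncand = pos

            for q in range(mandatory.shape[0]):
                c = mandatory[q]
                found = False
                for j in range(ncand):
                    if cand[j] == c:
                        found = True
                        break
                if not found:
                    cand[ncand] = c
                    ncand += 1

            for j in range(ncand):
                if use_weights:
                    wts[j] = weights[block_of_var[cand[j]]]
                else:
                    wts[j] = 1.0

            bj, thr, raw, wc = best_split(X, orows, t_s, s_s, cand, wts, ncand)
            if bj >= 0:
                bv = cand[bj]
                for i in range(ns):
                    tmp[i] = rows[start + i]
                nl = 0
                for i in range(ns):
                    if X[tmp[i], bv] <= thr:
                        rows[start + nl] = tmp[i]
                        nl += 1
                pos2 = start + nl
                for i in range(ns):
                    if X[tmp[i], bv] > thr:
                        rows[pos2] = tmp[i]
                        pos2 += 1
                feature[node] = bv
                thresh[node] = thr
                lid = n_nodes
                rid = n_nodes + 1
                n_nodes += 2
                left_c[node] = lid
                right_c[node] = rid
                st_node[top] = lid
                st_start[top] = start
                st_end[top] = start + nl
                top += 1
                st_node[top] = rid
                st_start[top] = start + nl
                st_end[top] = end
                top += 1
                split_done = True

        if not split_done:
            leaf_slot[node] = n_leaves
            leaf_chf(t_s, s_s, grid, chf[n_leaves])
            n_leaves += 1

    return (
        feature[:n_nodes].copy(),
        thresh[:n_nodes].copy(),
        left_c[:n_nodes].copy(),
        right_c[:n_nodes].copy(),
        leaf_slot[:n_nodes].copy(),
        chf[:n_leaves].copy(),
    )


@nb.njit(cache=True)
def bootstrap_inbag(n):
    """Bootstrap sample of size n with replacement; returns the drawn row
    ids and the per-observation inclusion counts."""
    rows = np.empty(n, np.int64)
    counts = np.zeros(n, np.int32)
    for i in range(n):
        r = np.random.randint(0, n)
        rows[i] = r
        counts[r] += 1
    return rows, counts


@nb.njit(cache=True)
def route(Xn, feature, thresh, left_c, right_c, leaf_slot):
    """Route each row of Xn down one tree; returns the leaf slot per row."""
    n = Xn.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        node = 0
        while leaf_slot[node] < 0:
            if Xn[i, feature[node]] <= thresh[node]:
                node = left_c[node]
            else:
                node = right_c[node]
        out[i] = leaf_slot[node]
    return out
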