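"""Numba kernel for the on-lattice tumor/stroma simulator.

One call advances a lattice through a baseline phase followed by a therapy
phase.  Cells are updated asynchronously in a fresh uniform random order each
step; per cell at most one event is drawn, with precedence death -> division
-> migration.  Division and migration require an empty neighbor site (chosen
uniformly); lattice boundaries are fixed (no wrap-around).  Stroma and
excluded sites never change.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def simulate_kernel(state, niche, off,
                    p_div_base, p_die_base, p_move,
                    p_div_out, p_div_niche, p_die_t,
                    steps_baseline, steps_therapy, seed):
    np.random.seed(seed)
    H, W = state.shape
    total = steps_baseline + steps_therapy
    n_hist = np.zeros(total + 1, np.int64)
    div_hist = np.zeros(total, np.int64)
    die_hist = np.zeros(total, np.int64)
    mov_hist = np.zeros(total, np.int64)
    n0 = 0
    for i in range(H):
        for j in range(W):
            if state[i, j] == 1:
                n0 += 1
    n_hist[0] = n0
    K = off.shape[0]
    ci = np.empty(H * W, np.int64)
    cj = np.empty(H * W, np.int64)
    ni = np.empty(K, np.int64)
    nj = np.empty(K, np.int64)
    for step in range(total):
        therapy = step >= steps_baseline
        # collect live cells (positions at step start)
        n = 0
        for i in range(H):
            for j in range(W):
                if state[i, j] == 1:
                    ci[n] = i
                    cj[n] = j
                    n += 1
        if n == 0:
            break  # extinct; remaining history stays at zero
        # fresh uniform permutation of the update order (Fisher-Yates)
        for k in range(n - 1, 0, -1):
            m = np.random.randint(0, k + 1)
            ti = ci[k]; ci[k] = ci[m]; ci[m] = ti
            tj = cj[k]; cj[k] = cj[m]; cj[m] = tj
        pdie = p_die_t if therapy else p_die_base
        ndiv = 0
        ndie = 0
        nmov = 0
        for k in range(n):
            i = ci[k]
            j = cj[k]
            if np.random.random() < pdie:
                state[i, j] = 0
                ndie += 1
                continue
            if therapy:
                pd = p_div_niche if niche[i, j] else p_div_out
            else:
                pd = p_div_base
            if np.random.random() < pd:
                cnt = 0
                for q in range(K):
                    a = i + off[q, 0]
                    b = j + off[q, 1]
                    if 0 <= a < H and 0 <= b < W and state[a, b] == 0:
                        ni[cnt] = a
                        nj[cnt] = b
                        cnt += 1
                if cnt > 0:
                    c = np.random.randint(0, cnt)
                    state[ni[c], nj[c]] = 1
                    ndiv += 1
            elif np.random.random() < p_move:
                cnt = 0
                for q in range(K):
                    a = i + off[q, 0]
                    b = j + off[q, 1]
                    if 0 <= a < H and 0 <= b < W and state[a, b] == 0:
                        ni[cnt] = a
                        nj[cnt] = b
                        cnt += 1
                if cnt > 0:
                    c = np.random.randint(0, cnt)
                    state[i, j] = 0
                    state[ni[c], nj[c]] = 1
                    nmov += 1
        n_hist[step + 1] = n_hist[step] + ndiv - ndie
        div_hist[step] = ndiv
        die_hist[step] = ndie
        mov_hist[step] = nmov
    return n_hist, div_hist, die_hist, mov_hist
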