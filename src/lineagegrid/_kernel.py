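"""Numba kernels for the stochastic cell phase of one time step.

The grid is sampled N times per time unit (N = current cell count, read
at the start of the step), with replacement, uniformly among *currently*
occupied spots, so the evolving occupancy is visible within the step.
Within one sampling, division, death and migration are evaluated as
sequential Bernoulli trials in that fixed order; later trials are
skipped if the sampled cell was removed or converted by an earlier one.

Occupancy is tracked with a swap-remove coordinate list plus a reverse
index grid so that sampling and removal are O(1).  All randomness comes
from numba's numpy random state, seeded once per run via
:func:`seed_rng`, which makes runs bit-reproducible for a given seed.
"""

import numpy as np
from numba import njit

EMPTY = 0
STEM = 1
TA = 2
DIFF = 3

_DR = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_DC = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _pick_neighbor(n, r, c):
    """Uniform draw among the in-grid Moore neighbors of (r, c)."""
    m = 0
    for k in range(8):
        rr = r + _DR[k]
        cc = c + _DC[k]
        if 0 <= rr < n and 0 <= cc < n:
            m += 1
    j = np.random.randint(m)
    for k in range(8):
        rr = r + _DR[k]
        cc = c + _DC[k]
        if 0 <= rr < n and 0 <= cc < n:
            if j == 0:
                return rr, cc
            j -= 1
    return -1, -1  # unreachable


@njit(cache=True)
def _add(grid, occ_r, occ_c, occ_idx, n_cells, r, c, kind):
    grid[r, c] = kind
    occ_r[n_cells] = r
    occ_c[n_cells] = c
    occ_idx[r, c] = n_cells
    return n_cells + 1


@njit(cache=True)
def _remove(grid, occ_r, occ_c, occ_idx, n_cells, r, c):
    idx = occ_idx[r, c]
    last = n_cells - 1
    lr = occ_r[last]
    lc = occ_c[last]
    occ_r[idx] = lr
    occ_c[idx] = lc
    occ_idx[lr, lc] = idx
    occ_idx[r, c] = -1
    grid[r, c] = EMPTY
    return last


@njit(cache=True)
def _migrate(grid, occ_r, occ_c, occ_idx, n, r, c):
    tr, tc = _pick_neighbor(n, r, c)
    if grid[tr, tc] == EMPTY:
        grid[tr, tc] = grid[r, c]
        grid[r, c] = EMPTY
        idx = occ_idx[r, c]
        occ_idx[r, c] = -1
        occ_r[idx] = tr
        occ_c[idx] = tc
        occ_idx[tr, tc] = idx


@njit(cache=True)
def step_cells(
    grid,
    occ_r,
    occ_c,
    occ_idx,
    n_cells,
    z,
    w,
    p_div,
    p0_self,
    h,
    p_sdeath,
    p_ddeath,
    p_mig,
    q_div,
    h2,
    q_tdeath,
    three_comp,
    use_feedback,
):
    """One cell-phase time unit; returns the updated cell count."""
    n = grid.shape[0]
    n0 = n_cells
    for _ in range(n0):
        if n_cells == 0:
            break
        k = np.random.randint(n_cells)
        r = occ_r[k]
        c = occ_c[k]
        kind = grid[r, c]
        gone = False  # removed or converted: skip later trials
        if kind == STEM:
            if np.random.random() < p_div:
                tr, tc = _pick_neighbor(n, r, c)
                if grid[tr, tc] == EMPTY:
                    if use_feedback:
                        p_self = p0_self / (1.0 + h * z[r, c])
                    else:
                        p_self = p0_self
                    if np.random.random() < p_self:
                        n_cells = _add(grid, occ_r, occ_c, occ_idx, n_cells, tr, tc, STEM)
                    else:
                        child = TA if three_comp else DIFF
                        n_cells = _add(grid, occ_r, occ_c, occ_idx, n_cells, tr, tc, child)
                        grid[r, c] = child
                        gone = True
            if not gone and np.random.random() < p_sdeath:
                n_cells = _remove(grid, occ_r, occ_c, occ_idx, n_cells, r, c)
                gone = True
        elif kind == TA:
            if np.random.random() < q_div:
                tr, tc = _pick_neighbor(n, r, c)
                if grid[tr, tc] == EMPTY:
                    q_self = 1.0 - 1.0 / (1.0 + h2 * w[r, c])
                    if np.random.random() < q_self:
                        n_cells = _add(grid, occ_r, occ_c, occ_idx, n_cells, tr, tc, TA)
                    else:
                        n_cells = _add(grid, occ_r, occ_c, occ_idx, n_cells, tr, tc, DIFF)
                        grid[r, c] = DIFF
                        gone = True
            if not gone and np.random.random() < q_tdeath:
                n_cells = _remove(grid, occ_r, occ_c, occ_idx, n_cells, r, c)
                gone = True
        else:  # DIFF
            if np.random.random() < p_ddeath:
                n_cells = _remove(grid, occ_r, occ_c, occ_idx, n_cells, r, c)
                gone = True
        if not gone and np.random.random() < p_mig:
            _migrate(grid, occ_r, occ_c, occ_idx, n, r, c)
    return n_cells
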