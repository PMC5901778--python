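"""Jitted run-to-confluence kernel.

Implements exactly the rules of :mod:`biofilmca.model` (one birth attempt
then one detachment attempt per step, drafting, truncated shoves, periodic
boundaries) on a flat occupied-site index for O(1) uniform cell picks.
The random stream is numba's per-thread legacy RandomState, seeded once per
run; it differs from the Python engine's stream, so the two engines agree
in distribution, not trajectory-by-trajectory.

Counter semantics (shared with the Python engine):

* ``births`` — division events (a newborn was created, even if it was
  immediately lost in a shove);
* ``shove_removals`` — shove losers removed because the resident's
  neighborhood was full;
* ``detachments`` — detach events; ``relocation_removals`` — detached cells
  whose landing site was occupied.

Bookkeeping invariant: ``final_count = initial_count + births −
shove_removals − relocation_removals``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_kernel"]

# Termination status codes returned by the kernel.
STATUS_THRESHOLD = 0
STATUS_MAX_STEPS = 1
STATUS_EXTINCT = 2


@njit(cache=True)
def run_kernel(grid, p_b, p_s, p_d, max_dx, threshold_count, max_steps, seed):
    """Drive ``grid`` (int8, modified in place) to the occupancy threshold.

    Returns (steps, births, shove_removals, detachments,
    relocation_removals, status).
    """
    np.random.seed(seed)
    H, W = grid.shape
    cap = H * W

    # Occupied-site list plus reverse index for O(1) pick/insert/remove.
    xs = np.empty(cap, np.int32)
    ys = np.empty(cap, np.int32)
    idx = np.full((H, W), -1, np.int32)
    n = 0
    for y in range(H):
        for x in range(W):
            if grid[y, x] != 0:
                xs[n] = x
                ys[n] = y
                idx[y, x] = n
                n += 1

    births = 0
    shove_rem = 0
    detach = 0
    reloc_rem = 0
    steps = 0
    status = STATUS_MAX_STEPS

    if n >= threshold_count:
        return steps, births, shove_rem, detach, reloc_rem, STATUS_THRESHOLD
    if n == 0:
        return steps, births, shove_rem, detach, reloc_rem, STATUS_EXTINCT

    ex = np.empty(8, np.int32)
    ey = np.empty(8, np.int32)

    while steps < max_steps:
        steps += 1

        # ---------------- birth sub-step ----------------
        if np.random.random() < p_b:
            pi = np.random.randint(n)
            px = xs[pi]
            py = ys[pi]
            pc = grid[py, px]
            births += 1

            # Empty Moore neighbors of the parent.
            ne = 0
            for dy in range(-1, 2):
                for dx in range(-1, 2):
                    if dx == 0 and dy == 0:
                        continue
                    qx = (px + dx) % W
                    qy = (py + dy) % H
                    if grid[qy, qx] == 0:
                        ex[ne] = qx
                        ey[ne] = qy
                        ne += 1
            if ne > 0:
                j = np.random.randint(ne)
                qx = ex[j]
                qy = ey[j]
                grid[qy, qx] = pc
                xs[n] = qx
                ys[n] = qy
                idx[qy, qx] = n
                n += 1
            else:
                # Shove a uniformly chosen resident neighbor (all occupied).
                k = np.random.randint(8)
                t = 0
                rx = px
                ry = py
                for dy in range(-1, 2):
                    for dx in range(-1, 2):
                        if dx == 0 and dy == 0:
                            continue
                        if t == k:
                            rx = (px + dx) % W
                            ry = (py + dy) % H
                        t += 1
                rc = grid[ry, rx]

                # Empty Moore neighbors of the resident's original site.
                ne = 0
                for dy in range(-1, 2):
                    for dx in range(-1, 2):
                        if dx == 0 and dy == 0:
                            continue
                        qx = (rx + dx) % W
                        qy = (ry + dy) % H
                        if grid[qy, qx] == 0:
                            ex[ne] = qx
                            ey[ne] = qy
                            ne += 1

                resident_loses = np.random.random() < p_s
                if resident_loses:
                    grid[ry, rx] = pc  # newborn takes the resident's site
                    if ne > 0:
                        j = np.random.randint(ne)
                        qx = ex[j]
                        qy = ey[j]
                        grid[qy, qx] = rc
                        xs[n] = qx
                        ys[n] = qy
                        idx[qy, qx] = n
                        n += 1
                    else:
                        shove_rem += 1  # resident lost with the outflow
                else:
                    if ne > 0:
                        j = np.random.randint(ne)
                        qx = ex[j]
                        qy = ey[j]
                        grid[qy, qx] = pc
                        xs[n] = qx
                        ys[n] = qy
                        idx[qy, qx] = n
                        n += 1
                    else:
                        shove_rem += 1  # newborn lost with the outflow

        # ---------------- detachment sub-step ----------------
        if n > 0:
            di = np.random.randint(n)
            x = xs[di]
            y = ys[di]
            ux = (x - 1) % W
            if grid[y, ux] == 0 and p_d > 0.0 and np.random.random() < p_d:
                detach += 1
                color = grid[y, x]
                # Remove from grid and occupied list (swap-remove).
                grid[y, x] = 0
                last = n - 1
                lx_ = xs[last]
                ly_ = ys[last]
                xs[di] = lx_
                ys[di] = ly_
                idx[ly_, lx_] = di
                idx[y, x] = -1
                n = last
                # Relocation draw (origin already vacated).
                ddx = np.random.randint(0, max_dx + 1)
                ddy = np.random.randint(-ddx, ddx + 1)
                lx = (x + ddx) % W
                ly = (y + ddy) % H
                if grid[ly, lx] == 0:
                    grid[ly, lx] = color
                    xs[n] = lx
                    ys[n] = ly
                    idx[ly, lx] = n
                    n += 1
                else:
                    reloc_rem += 1

        if n == 0:
            status = STATUS_EXTINCT
            break
        if n >= threshold_count:
            status = STATUS_THRESHOLD
            break

    return steps, births, shove_rem, detach, reloc_rem, status
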