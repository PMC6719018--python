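"""Numba-compiled inner loops for the dynamics engine.

The jitted pair kernel fuses minimum-image displacement, the 12-6 +
Debye-Hückel pair terms (shifted at the cutoff) and per-bead force
accumulation into one pass over the neighbour list.  The numpy implementation
in :mod:`nanocg.forcefield` remains the reference; the two are cross-checked
in the test suite.
"""

import numba
import numpy as np


@numba.njit(cache=True, fastmath=True)
def pair_forces(pos, pi, pj, sidx, r0_t, eps_t, qq_t, hs_shift_t,
                lam, el_unit, rc, box, periodic, fbead):
    """Accumulate pair forces into fbead; return (e_hs, e_el, n_overlap)."""
    e_hs = 0.0
    e_el = 0.0
    n_overlap = 0
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        if periodic:
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r >= rc:
            continue
        if r < 0.5:
            r = 0.5
            n_overlap += 1
        sa = sidx[a]
        sb = sidx[b]
        r0 = r0_t[sa, sb]
        eps = eps_t[sa, sb]
        qq = qq_t[sa, sb]
        rinv = 1.0 / r
        x2 = (r0 * rinv) * (r0 * rinv)
        x6 = x2 * x2 * x2
        x12 = x6 * x6
        e_hs += eps * (x12 - 2.0 * x6) - hs_shift_t[sa, sb]
        expl = np.exp(-r / lam)
        e_el += qq * (expl * rinv - el_unit)
        dudr = (-12.0 * eps * rinv * (x12 - x6)
                - qq * expl * rinv * (1.0 / lam + rinv))
        # cap the radial force so transient hard overlaps stay integrable
        if dudr < -1e3:
            dudr = -1e3
        elif dudr > 1e3:
            dudr = 1e3
        fscale = -dudr * rinv
        fx = fscale * dx
        fy = fscale * dy
        fz = fscale * dz
        fbead[a, 0] += fx
        fbead[a, 1] += fy
        fbead[a, 2] += fz
        fbead[b, 0] -= fx
        fbead[b, 1] -= fy
        fbead[b, 2] -= fz
    return e_hs, e_el, n_overlap
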