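"""Numba kernels for ray tracing and backprojection.

Both kernels work in physical mm with the virtual detector placed at the
isocenter (channel coordinate t = impact-parameter-like coordinate; the
ray through channel t of view beta runs from the source at
RF*(cos b, sin b) through the point t*(-sin b, cos b)).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def forward_kernel(mu, spacing, ox, oy, cosb, sinb, rf, tvals, step, rclip, out):
    """Line integrals of ``mu`` (2D grid) along all fan rays.

    mu : (H, W) attenuation per mm on a grid with pixel pitch ``spacing``
         centered at (ox, oy).
    tvals : channel coordinates on the virtual detector at isocenter.
    step : ray sampling step in mm (midpoint rule, bilinear interpolation).
    rclip : radius of a circle centered at (ox, oy) guaranteed to contain
            all nonzero pixels; rays missing it contribute 0.
    out : (n_angles, n_channels), overwritten.
    """
    na = cosb.shape[0]
    nc = tvals.shape[0]
    h, w = mu.shape
    ch = (h - 1) / 2.0
    cw = (w - 1) / 2.0
    for a in range(na):
        sx = rf * cosb[a]
        sy = rf * sinb[a]
        ex = -sinb[a]
        ey = cosb[a]
        for ic in range(nc):
            t = tvals[ic]
            dx = t * ex - sx
            dy = t * ey - sy
            dl = np.sqrt(dx * dx + dy * dy)
            dx /= dl
            dy /= dl
            fx = sx - ox
            fy = sy - oy
            b = fx * dx + fy * dy
            disc = b * b - (fx * fx + fy * fy - rclip * rclip)
            if disc <= 0.0:
                out[a, ic] = 0.0
                continue
            sq = np.sqrt(disc)
            s0 = -b - sq
            s1 = -b + sq
            n = int((s1 - s0) / step) + 1
            acc = 0.0
            for k in range(n):
                s = s0 + (k + 0.5) * step
                px = sx + s * dx
                py = sy + s * dy
                fc = (px - ox) / spacing + cw
                fr = (py - oy) / spacing + ch
                if fc < 0.0 or fr < 0.0 or fc > w - 1 or fr > h - 1:
                    continue
                c0 = int(fc)
                r0 = int(fr)
                if c0 >= w - 1:
                    c0 = w - 2
                if r0 >= h - 1:
                    r0 = h - 2
                wc = fc - c0
                wr = fr - r0
                acc += (
                    mu[r0, c0] * (1 - wr) * (1 - wc)
                    + mu[r0, c0 + 1] * (1 - wr) * wc
                    + mu[r0 + 1, c0] * wr * (1 - wc)
                    + mu[r0 + 1, c0 + 1] * wr * wc
                )
            out[a, ic] = acc * step


@njit(cache=True, fastmath=True)
def backproject_kernel(q, cosb, sinb, rf, t0, dt, spacing, ox, oy, n, ilo, ihi, dbeta, out):
    """Distance-weighted fan-beam backprojection of filtered rows ``q``.

    q : (n_angles, n_channels) filtered projections.
    t0, dt : coordinate of channel 0 and pitch on the virtual detector.
    n : output matrix size; grid pitch ``spacing`` centered at (ox, oy).
    ilo, ihi : inclusive fractional-channel-index interval outside which a
        projected pixel receives no contribution (restricts backprojection
        to e.g. the measured channel block).
    out : (n, n), overwritten.
    """
    na = cosb.shape[0]
    nc = q.shape[1]
    c0 = (n - 1) / 2.0
    for r in range(n):
        y = oy + (r - c0) * spacing
        for c in range(n):
            x = ox + (c - c0) * spacing
            acc = 0.0
            for a in range(na):
                u = rf - (x * cosb[a] + y * sinb[a])
                if u < 1.0:
                    continue
                t = rf * (-x * sinb[a] + y * cosb[a]) / u
                fi = (t - t0) / dt
                if fi < ilo or fi > ihi:
                    continue
                i0 = int(fi)
                if i0 >= nc - 1:
                    i0 = nc - 2
                wi = fi - i0
                val = q[a, i0] * (1 - wi) + q[a, i0 + 1] * wi
                acc += val * rf * rf / (u * u)
            out[r, c] = acc * dbeta
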