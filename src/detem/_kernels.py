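"""Numba hot loops for per-spot dose accumulation.

One beam's spots are parallel rays; every evaluation voxel is described by
its beam-frame coordinates (u, v lateral in the beam's-eye view, t geometric
depth along the beam axis).  Each spot carries its own cumulative WEPL profile
along its central axis sampled on a uniform t grid, a tabulated depth-dose
curve row (indexed by water-equivalent depth), and precomputed range/lateral
scattering constants.  Voxels are pre-bucketed on a coarse (u, v) grid so a
spot only visits candidates inside its lateral cutoff window.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True, fastmath=True)
def accumulate_spots(
    vox_u, vox_v, vox_t,            # float32[n_vox] beam-frame voxel coords
    bucket_start, bucket_idx,       # CSR buckets of voxels on the (u,v) bin grid
    u0, v0, binw, nbu, nbv,
    spot_u, spot_v,                 # effective (shift-corrected) spot BEV positions
    spot_wepl, t0, dt,              # float32[n_spot, n_t] axis WEPL on uniform t grid
    dd_table, dd_step, wed_max,     # float32[n_e, L] depth-dose rows; support per row
    spot_row,                       # int32[n_spot] row into dd_table
    spot_range, spot_norm, spot_weight,
    sigma_air2, mcs2,               # scalar sigma_air^2; float32[n_spot] (f*R)^2
    cutoff2,                        # lateral cutoff in units of sigma^2 (e.g. 3.5^2)
    out,                            # float64[n_vox] accumulator
):
    n_spot = spot_u.shape[0]
    n_t = spot_wepl.shape[1]
    for s in range(n_spot):
        w8 = spot_weight[s]
        if w8 == 0.0:
            continue
        norm = spot_norm[s]
        if norm == 0.0:
            continue
        su = spot_u[s]
        sv = spot_v[s]
        row = spot_row[s]
        wmax = wed_max[row]
        rng = spot_range[s]
        m2 = mcs2[s]
        sigmax2 = sigma_air2 + m2
        cut = np.sqrt(cutoff2 * sigmax2)
        cut2 = cut * cut
        ia = int(np.floor((su - cut - u0) / binw))
        ib = int(np.floor((su + cut - u0) / binw))
        ja = int(np.floor((sv - cut - v0) / binw))
        jb = int(np.floor((sv + cut - v0) / binw))
        if ia < 0:
            ia = 0
        if ja < 0:
            ja = 0
        if ib > nbu - 1:
            ib = nbu - 1
        if jb > nbv - 1:
            jb = nbv - 1
        for bu in range(ia, ib + 1):
            for bv in range(ja, jb + 1):
                b = bu * nbv + bv
                for ptr in range(bucket_start[b], bucket_start[b + 1]):
                    j = bucket_idx[ptr]
                    du = vox_u[j] - su
                    dvv = vox_v[j] - sv
                    r2 = du * du + dvv * dvv
                    if r2 > cut2:
                        continue
                    # axis WEPL at the voxel's geometric depth
                    ft = (vox_t[j] - t0) / dt
                    if ft <= 0.0:
                        w = spot_wepl[s, 0]
                    else:
                        k = int(ft)
                        if k >= n_t - 1:
                            w = spot_wepl[s, n_t - 1]
                        else:
                            f = ft - k
                            w = spot_wepl[s, k] * (1.0 - f) + spot_wepl[s, k + 1] * f
                    if w >= wmax:
                        continue
                    fd = w / dd_step
                    kd = int(fd)
                    f = fd - kd
                    dd = dd_table[row, kd] * (1.0 - f) + dd_table[row, kd + 1] * f
                    if dd <= 0.0:
                        continue
                    frac = w / rng
                    if frac > 1.0:
                        frac = 1.0
                    sig2 = sigma_air2 + m2 * frac * frac * frac
                    if r2 > cutoff2 * sig2:
                        continue
                    g = np.exp(-0.5 * r2 / sig2) / (TWO_PI * sig2)
                    out[j] += w8 * norm * dd * g
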