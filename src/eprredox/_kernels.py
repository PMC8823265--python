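"""Numba inner loops for the plane-integral projector and its adjoint.

The projected field offset of a voxel factorizes over axes,
``t(i,j,k) = ax[i] + ay[j] + az[k]`` with ``ax[i] = G d_x x_i`` etc., so the
scatter/gather loops touch each voxel once.  Voxel mass is split linearly
between the two nearest field bins; mass falling outside ``[bin 0, bin n-1]``
is dropped (no wrap-around) and reported, and the gather applies the exact
transpose of the same weights so the operator pair passes the adjoint
dot-product test to machine precision.
"""

import numba
import numpy as np


@numba.njit(cache=True, fastmath=False)
def scatter_project(vol, ax, ay, az, b0, inv_db, nbins):
    """Bin voxel mass onto the field axis along one direction.

    Returns ``(hist, dropped)`` where ``dropped`` is the total mass that
    projected outside the field axis.
    """
    hist = np.zeros(nbins, dtype=np.float64)
    dropped = 0.0
    nx, ny, nz = vol.shape
    for i in range(nx):
        ti = ax[i] - b0
        for j in range(ny):
            tij = ti + ay[j]
            for k in range(nz):
                m = vol[i, j, k]
                if m == 0.0:
                    continue
                u = (tij + az[k]) * inv_db
                j0 = int(np.floor(u))
                if j0 < 0 or j0 >= nbins - 1:
                    dropped += m
                    continue
                w = u - j0
                hist[j0] += m * (1.0 - w)
                hist[j0 + 1] += m * w
    return hist, dropped


@numba.njit(cache=True, fastmath=False)
def gather_backproject(out, q, ax, ay, az, b0, inv_db, scale):
    """Transpose of :func:`scatter_project`: linear read-back of a profile.

    Adds ``scale * interp(q, t(i,j,k))`` into ``out`` in place.
    """
    nbins = q.shape[0]
    nx, ny, nz = out.shape
    for i in range(nx):
        ti = ax[i] - b0
        for j in range(ny):
            tij = ti + ay[j]
            for k in range(nz):
                u = (tij + az[k]) * inv_db
                j0 = int(np.floor(u))
                if j0 < 0 or j0 >= nbins - 1:
                    continue
                w = u - j0
                out[i, j, k] += scale * ((1.0 - w) * q[j0] + w * q[j0 + 1])
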