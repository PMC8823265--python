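"""Voxelwise decay-rate mapping: the redox-sensitive readout.

The bioreduction of a nitroxyl radical to its EPR-silent hydroxylamine
makes the per-voxel signal decay ``S(t) = A0 exp(-k t)``; the rate ``k``
reports the local reducing capacity of the tissue.  A decay-rate map is
obtained by fitting this model voxel by voxel across a time series of
reconstructed volumes, gated by an intensity threshold on the first frame
to keep background noise out of the computation.

The fit is a damped Gauss-Newton on ``(A0, k)`` initialized from the
log-linear ordinary least-squares solution, vectorized over all masked
voxels at once; a pure log-linear fit is available as an option.  Rates
carry the reciprocal of the series' time unit, so a series timed in
minutes yields k in min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import ImageSeries, VolumeImage

__all__ = [
    "DecayRateMap",
    "threshold_mask",
    "fit_decay_map",
    "decay_histogram_stats",
    "roi_mean_rates",
    "square_roi",
]


@dataclass
class DecayRateMap:
    """Per-voxel decay rates with validity mask and fit diagnostics.

    ``rates`` (1/time-unit) and ``amplitudes`` are defined only where
    ``mask`` is true; ``fit_quality`` holds the per-voxel R^2.
    """

    rates: np.ndarray
    amplitudes: np.ndarray
    mask: np.ndarray
    fit_quality: np.ndarray
    time_unit: str = "s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (
            self.rates.shape
            == self.amplitudes.shape
            == self.mask.shape
            == self.fit_quality.shape
        ):
            raise ValueError("all decay-map fields must share one shape")
        if not np.all(np.isfinite(self.rates[self.mask])):
            raise ValueError("masked rates must be finite")

    def masked_rates(self) -> np.ndarray:
        return self.rates[self.mask]


def threshold_mask(v: VolumeImage | np.ndarray, fraction: float) -> np.ndarray:
    """Voxels at or above ``fraction`` of the global maximum intensity."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    data = v.data if isinstance(v, VolumeImage) else np.asarray(v)
    return data >= fraction * data.max()


def _loglinear_fit(S: np.ndarray, t: np.ndarray):
    """OLS of log S against t per voxel, non-positive samples clipped."""
    floor = 1e-12 * max(S.max(), 1e-300)
    logS = np.log(np.clip(S, floor, None))
    tbar = t.mean()
    denom = ((t - tbar) ** 2).sum()
    slope = ((t - tbar)[None, :] * (logS - logS.mean(axis=1, keepdims=True))).sum(
        axis=1
    ) / denom
    intercept = logS.mean(axis=1) - slope * tbar
    return np.exp(intercept), -slope  # A0, k


def _gauss_newton_fit(
    S: np.ndarray, t: np.ndarray, A0: np.ndarray, k0: np.ndarray,
    max_iter: int = 200, tol: float = 1e-12,
):
    """Vectorized damped Gauss-Newton for S ~ A exp(-k t), per voxel."""
    A = A0.copy()
    k = k0.copy()
    lam = np.full(A.shape, 1e-3)  # Levenberg damping per voxel
    active = np.ones(A.shape, dtype=bool)
    converged = np.zeros(A.shape, dtype=bool)

    def cost(Av, kv):
        r = Av[:, None] * np.exp(-np.outer(kv, t)) - S
        return (r * r).sum(axis=1)

    c = cost(A, k)
    for _ in range(max_iter):
        if not active.any():
            break
        E = np.exp(-np.outer(k, t))  # (nvox, nt)
        r = A[:, None] * E - S
        jA = E
        jk = -(A[:, None]) * t[None, :] * E
        gA = (jA * r).sum(axis=1)
        gk = (jk * r).sum(axis=1)
        hAA = (jA * jA).sum(axis=1)
        hkk = (jk * jk).sum(axis=1)
        hAk = (jA * jk).sum(axis=1)
        hAA_d = hAA * (1.0 + lam)
        hkk_d = hkk * (1.0 + lam)
        det = hAA_d * hkk_d - hAk * hAk
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        dA = -(hkk_d * gA - hAk * gk) / det
        dk = -(hAA_d * gk - hAk * gA) / det
        A_new = A + np.where(active, dA, 0.0)
        k_new = k + np.where(active, dk, 0.0)
        c_new = cost(A_new, k_new)
        better = c_new <= c
        accept = active & better
        A = np.where(accept, A_new, A)
        k = np.where(accept, k_new, k)
        lam = np.where(accept, lam * 0.5, lam * 4.0)
        np.clip(lam, 1e-12, 1e12, out=lam)
        step_small = (np.abs(dA) <= tol * (1.0 + np.abs(A))) & (
            np.abs(dk) <= tol * (1.0 + np.abs(k))
        )
        converged |= active & accept & step_small
        c = np.where(accept, c_new, c)
        active &= ~ (accept & step_small)
    return A, k, converged | ~active | (c <= 1e-28 * max(float((S * S).sum()), 1e-300))


def fit_decay_map(
    s: ImageSeries,
    fraction: float = 0.25,
    n_frames: int | None = None,
    method: str = "nonlinear",
    max_iter: int = 200,
) -> DecayRateMap:
    """Fit ``S(t) = A0 exp(-k t)`` voxel by voxel over an image series.

    The mask is ``fraction`` of the first frame's maximum; ``n_frames``
    restricts the fit to the earliest frames (later frames of a decaying
    series have lower SNR).  ``method`` is ``"nonlinear"`` (log-linear
    initialized Gauss-Newton, the default) or ``"loglinear"``.  Voxels whose
    nonlinear fit fails to converge within ``max_iter`` iterations are
    removed from the mask; their count is reported in ``meta``.
    """
    if len(s) < 2:
        raise ValueError("need at least two frames to fit a decay")
    n_frames = len(s) if n_frames is None else min(n_frames, len(s))
    if n_frames < 2:
        raise ValueError("need at least two frames to fit a decay")
    t = s.times[:n_frames].astype(float)
    if np.ptp(t) == 0:
        raise ValueError("degenerate series: all frame times equal")

    mask = threshold_mask(s.frames[0], fraction)
    stack = s.stack()[:n_frames]
    S = stack[:, mask].T  # (nvox, nt)

    shape = s.frames[0].data.shape
    rates = np.zeros(shape)
    amps = np.zeros(shape)
    r2 = np.zeros(shape)
    n_failed = 0
    if S.shape[0] > 0:
        A0, k0 = _loglinear_fit(S, t)
        if method == "loglinear":
            A, k = A0, k0
            ok = np.ones(A.shape, dtype=bool)
        elif method == "nonlinear":
            A, k, ok = _gauss_newton_fit(S, t, A0, k0, max_iter=max_iter)
        else:
            raise ValueError("method must be 'nonlinear' or 'loglinear'")
        pred = A[:, None] * np.exp(-np.outer(k, t))
        ss_res = ((S - pred) ** 2).sum(axis=1)
        ss_tot = ((S - S.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_vox = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
        ok &= np.isfinite(k) & np.isfinite(A)
        n_failed = int((~ok).sum())
        idx = np.flatnonzero(mask.ravel())
        flat_keep = idx[ok]
        new_mask = np.zeros(mask.size, dtype=bool)
        new_mask[flat_keep] = True
        mask = new_mask.reshape(shape)
        rates.ravel()[flat_keep] = k[ok]
        amps.ravel()[flat_keep] = A[ok]
        r2.ravel()[flat_keep] = r2_vox[ok]

    return DecayRateMap(
        rates, amps, mask, r2, time_unit=s.time_unit,
        meta={"n_frames": n_frames, "threshold_fraction": fraction,
              "n_failed": n_failed, "method": method},
    )


def decay_histogram_stats(m: DecayRateMap, bins=50) -> dict:
    """Histogram plus summary statistics of the masked decay rates."""
    vals = m.masked_rates()
    if vals.size == 0:
        raise ValueError("no valid voxels in the decay-rate map")
    if np.ptp(vals) <= 1e-12 * max(1.0, abs(float(vals.mean()))):
        span = (float(vals.mean()) - 0.5, float(vals.mean()) + 0.5)
    else:
        span = (float(vals.min()), float(vals.max()))
    counts, edges = np.histogram(vals, bins=bins, range=span)
    return {
        "counts": counts,
        "bin_edges": edges,
        "median": float(np.median(vals)),
        "mean": float(vals.mean()),
        "variance": float(vals.var()),
        "count": int(vals.size),
    }


def square_roi(i0: int, j0: int, k: int, size: int = 5):
    """A size x size in-plane box on z-slice ``k``, as three index ranges."""
    return ((i0, i0 + size), (j0, j0 + size), (k, k + 1))


def roi_mean_rates(m: DecayRateMap, rois) -> list[dict]:
    """Mean masked decay rate inside each box region.

    Each ROI is three ``(start, stop)`` index ranges, one per array axis
    (the in-plane 5 x 5 boxes of practice come from :func:`square_roi` on a
    chosen slice).  An ROI with no valid voxels yields ``mean = nan``
    rather than an exception.
    """
    out = []
    shape = m.rates.shape
    for roi in rois:
        (a0, a1), (b0, b1), (c0, c1) = roi
        if not (0 <= a0 < a1 <= shape[0] and 0 <= b0 < b1 <= shape[1]
                and 0 <= c0 < c1 <= shape[2]):
            raise ValueError(f"ROI {roi} outside volume bounds {shape}")
        sub_mask = m.mask[a0:a1, b0:b1, c0:c1]
        sub_rate = m.rates[a0:a1, b0:b1, c0:c1]
        n_valid = int(sub_mask.sum())
        mean = float(sub_rate[sub_mask].mean()) if n_valid else float("nan")
        out.append({"mean": mean, "n_valid": n_valid, "roi": roi})
    return out
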