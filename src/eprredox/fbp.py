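"""Filtered back-projection of plane-integral spectral projections.

The conventional one-step 3D reconstruction: Tikhonov-regularized Wiener
deconvolution of the lineshape, the 3D-Radon inversion filter -- a
second-derivative (|k|^2 ramp) filter under a cosine apodization window --
and back-projection over the sphere.  The profile estimator
:func:`deconvolve_lineshape` integrates each first-derivative spectrum to
absorption form before dividing (the derivative lineshape has no DC
component, so plane-integral mass is only recoverable that way); the
filtered path inside :func:`fbp_reconstruct` divides directly by the
derivative transfer function because its filter removes DC regardless.
For plane integrals the inversion formula is

    f(r) = -1/(8 pi^2) integral_{S^2} d^2 xi  p''_xi ( xi . r ),

discretized with weight 4 pi / n per direction.  The absolute scale of a
discrete FBP depends on grid and filter conventions, so the output is
calibrated so that a unit impulse at the grid center reconstructs to unit
peak; image-quality metrics normalize away any remaining global scale.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq
from scipy.integrate import cumulative_trapezoid

from ._kernels import gather_backproject
from .forward import (
    LineshapeModel,
    SpectralProjectionSet,
    _absorption_kernel,
    _lineshape_kernel,
    convolve_same,
    double_integral,
)
from .volume import VolumeImage

__all__ = ["deconvolve_lineshape", "fbp_reconstruct"]


def _kernel_fft(kernel: np.ndarray, nfft: int) -> np.ndarray:
    """FFT of the convolution kernel, center rolled to index 0.

    With this phasing the padded FFT of a "same"-mode convolution equals the
    product of the profile FFT and this kernel FFT.
    """
    c = (kernel.size - 1) // 2
    padded = np.zeros(nfft)
    padded[: kernel.size] = kernel
    padded = np.roll(padded, -c)
    return rfft(padded)


def _measured_kernel(s: SpectralProjectionSet) -> np.ndarray:
    """Zero-gradient spectrum as a derivative kernel on the tap axis.

    The kernel tap for zero field offset sits at index ``(n - 1) // 2``,
    whereas the measured line center sits at field value 0 of the sweep
    axis (between bins when the point count is even), so the measured
    spectrum is resampled onto the centered tap axis before use.
    """
    if s.zero_gradient_spectrum is None:
        raise ValueError("projection set has no zero-gradient spectrum")
    area = double_integral(s.zero_gradient_spectrum, s.field_axis)
    if area <= 0:
        raise ValueError("zero-gradient spectrum has non-positive area")
    n = s.field_axis.size
    db = float(s.field_axis[1] - s.field_axis[0])
    taps = (np.arange(n) - (n - 1) // 2) * db
    resampled = np.interp(taps, s.field_axis, s.zero_gradient_spectrum,
                          left=0.0, right=0.0)
    return resampled / area


def _absorption_deconv_kernel(
    s: SpectralProjectionSet, m: LineshapeModel | None, use_zero_gradient: bool
) -> np.ndarray:
    """Absorption-shaped deconvolution kernel (unit area)."""
    db = float(s.field_axis[1] - s.field_axis[0])
    n = s.field_axis.size
    if use_zero_gradient:
        # integrate the measured first-derivative line to absorption form
        taps = (np.arange(n) - (n - 1) // 2) * db
        return cumulative_trapezoid(_measured_kernel(s), taps, initial=0.0)
    return _absorption_kernel(m if m is not None else LineshapeModel(), n, db)


def _deconvolve_core(
    spectra: np.ndarray,
    field_axis: np.ndarray,
    kernel_abs: np.ndarray,
    reg: float,
    nfft: int,
) -> np.ndarray:
    """Integrate, detrend, and Wiener-divide by the absorption line.

    The linear detrend anchors both ends of the integrated spectrum at
    zero: the truncated absorption tails leave a small residual at the
    sweep edges that would otherwise leak as a step into the padded FFT.
    """
    db = float(field_axis[1] - field_axis[0])
    n = field_axis.size
    integ = cumulative_trapezoid(spectra, field_axis, axis=-1, initial=0.0)
    integ = integ - integ[..., -1:] * np.linspace(0.0, 1.0, n)
    kf = _kernel_fft(kernel_abs, nfft)
    power = np.abs(kf) ** 2
    den = power + reg * power.max()
    prof_f = rfft(integ, n=nfft, axis=-1) * np.conj(kf) / den / db
    return irfft(prof_f, n=nfft, axis=-1)[..., :n]


def _filtered_fft(
    spectra: np.ndarray,
    kernel_deriv: np.ndarray,
    db: float,
    reg: float,
    nfft: int,
    n_out: int,
) -> np.ndarray:
    """Deconvolve (derivative kernel) and ramp-filter in one padded FFT pass.

    The 3D-Radon inversion filter removes DC regardless, so the filtered
    path divides directly by the first-derivative transfer function -- no
    integration step, hence no edge-leakage into the |k|^2 filter.
    """
    kf = _kernel_fft(kernel_deriv, nfft)
    power = np.abs(kf) ** 2
    den = power + reg * power.max()
    prof_f = rfft(spectra, n=nfft, axis=-1) * np.conj(kf) / den / db
    prof_f *= _radon_filter(nfft, db)
    return irfft(prof_f, n=nfft, axis=-1)[..., :n_out]


def deconvolve_lineshape(
    s: SpectralProjectionSet,
    m: LineshapeModel | None = None,
    reg: float = 1e-3,
    use_zero_gradient: bool = False,
) -> np.ndarray:
    """Estimate plane-integral profiles from first-derivative spectra.

    Each spectrum is integrated along the field axis and divided in the
    Fourier domain by the absorption lineshape's transfer function with
    Tikhonov regularization ``|L|^2 + reg max|L|^2``.  With
    ``use_zero_gradient=True`` the measured zero-gradient spectrum
    (integrated and normalized to unit area) is the kernel instead of the
    analytic model.
    """
    if reg <= 0:
        raise ValueError("reg must be > 0")
    kernel = _absorption_deconv_kernel(s, m, use_zero_gradient)
    n = s.field_axis.size
    nfft = next_fast_len(n + kernel.size - 1)
    return _deconvolve_core(s.spectra, s.field_axis, kernel, reg, nfft)


def _radon_filter(nfft: int, db: float) -> np.ndarray:
    """Second-derivative (-(2 pi nu)^2) filter with a cosine window."""
    nu = rfftfreq(nfft, db)
    nu_max = nu[-1]
    window = np.cos(np.pi * nu / (2.0 * nu_max))
    return -((2.0 * np.pi * nu) ** 2) * window


def _filtered_profiles(
    s: SpectralProjectionSet, m: LineshapeModel, reg: float, use_zero_gradient: bool
) -> np.ndarray:
    """Filtered (second-derivative) plane-integral profiles of all spectra."""
    db = float(s.field_axis[1] - s.field_axis[0])
    n = s.field_axis.size
    if use_zero_gradient:
        kernel = _measured_kernel(s)
    else:
        kernel = _lineshape_kernel(m, n, db)
    nfft = next_fast_len(2 * (n + kernel.size - 1))
    return _filtered_fft(s.spectra, kernel, db, reg, nfft, n)


def _backproject(
    filtered: np.ndarray,
    s: SpectralProjectionSet,
    out_template: VolumeImage,
) -> np.ndarray:
    n_dir = s.directions.n
    g_mm = s.protocol.gradient_magnitude / 1000.0
    db = float(s.field_axis[1] - s.field_axis[0])
    # -1/(8 pi^2) * (4 pi / n) * G^3 per direction
    weight = -(g_mm**3) / (2.0 * np.pi * n_dir)
    cx, cy, cz = out_template.coords()
    out = np.zeros(out_template.data.shape)
    b0 = float(s.field_axis[0])
    filtered = np.ascontiguousarray(filtered)
    for i in range(n_dir):
        d = s.directions.vectors[i]
        gather_backproject(
            out, filtered[i], g_mm * d[0] * cx, g_mm * d[1] * cy, g_mm * d[2] * cz,
            b0, 1.0 / db, weight,
        )
    return out


def _impulse_calibration(
    s: SpectralProjectionSet,
    m: LineshapeModel,
    template: VolumeImage,
    reg: float,
) -> float:
    """Reconstructed peak value of a unit impulse at the grid-center voxel.

    Uses the same forward discretization, deconvolution, filter and
    interpolation as the main pipeline, but evaluates the back-projection
    only at the impulse voxel, so the cost is one 1D pipeline per direction.
    """
    db = float(s.field_axis[1] - s.field_axis[0])
    n = s.field_axis.size
    g_mm = s.protocol.gradient_magnitude / 1000.0
    kernel = _lineshape_kernel(m, n, db)
    # voxel nearest the coordinate origin
    cx, cy, cz = template.coords()
    r0 = np.array([c[np.argmin(np.abs(c))] for c in (cx, cy, cz)])
    scale = template.voxel_volume * g_mm / db

    t = s.directions.vectors @ (g_mm * r0)  # projected offsets, one per direction
    u = (t - s.field_axis[0]) / db
    j0 = np.floor(u).astype(int)
    w = u - j0
    profiles = np.zeros((s.directions.n, n))
    rows = np.arange(s.directions.n)
    profiles[rows, j0] = (1.0 - w) * scale
    profiles[rows, j0 + 1] = w * scale
    spectra = convolve_same(profiles, kernel, db)
    nfft = next_fast_len(2 * (n + kernel.size - 1))
    filtered = _filtered_fft(spectra, kernel, db, reg, nfft, n)
    vals = (1.0 - w) * filtered[rows, j0] + w * filtered[rows, j0 + 1]
    weight = -(g_mm**3) / (2.0 * np.pi * s.directions.n)
    return float(weight * vals.sum())


def fbp_reconstruct(
    s: SpectralProjectionSet,
    m: LineshapeModel | None = None,
    matrix: int = 64,
    fov: float = 37.5,
    reg: float = 1e-3,
    use_zero_gradient: bool = False,
) -> VolumeImage:
    """One-step 3D filtered back-projection of a spectral projection set.

    Deconvolves the lineshape, applies the second-derivative/cosine filter
    and back-projects with weight ``4 pi / n`` per direction and the 3D
    Radon constant ``-1/(8 pi^2)``; the global scale is fixed by impulse
    calibration on the same geometry.
    """
    if s.directions.n < 1:
        raise ValueError("need at least one projection")
    if m is None:
        m = LineshapeModel()
    if s.spectra.shape[0] != s.directions.n:
        raise ValueError("direction/spectra count mismatch")
    template = VolumeImage(np.zeros((matrix,) * 3), fov)
    filtered = _filtered_profiles(s, m, reg, use_zero_gradient)
    out = _backproject(filtered, s, template)
    cal = _impulse_calibration(s, m, template, reg)
    if cal != 0:
        out = out / cal
    return template.with_data(out)
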