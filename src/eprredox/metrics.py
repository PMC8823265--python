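"""Image-quality assessment and spatial-resolution estimation.

Three indicators compare a reconstruction against a reference volume:

* NRMSE -- root-mean-square difference normalized by the reference's
  intensity range (lower is better);
* MAE -- mean absolute difference after each image is divided by its own
  maximum (lower is better; invariant to relative global scale);
* SSIM -- structural similarity (higher is better).  The default is the
  windowed mean-local form (3D Gaussian weighting, sigma 1.5, 11-voxel
  support, c1 = (0.01 L)^2, c2 = (0.03 L)^2); the single-window
  global-statistics form is exposed as a variant.

Two reference conventions are used in practice and named here: phantom
comparisons reference each method's own densest (2048-projection)
reconstruction; in-vivo-style comparisons reference the CS reconstruction
at the acquired count, because no low-noise reference exists.

The point-spread-function width is estimated by fitting a 1D intensity
profile as the convolution of the known ideal structure (a rod of given
width) with a Gaussian PSF.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf
from skimage.metrics import structural_similarity

from .volume import VolumeImage

__all__ = ["nrmse", "mae", "ssim", "psf_fwhm_estimate", "REFERENCE_PROTOCOLS"]

#: named comparison protocols: which reconstruction serves as reference
REFERENCE_PROTOCOLS = {
    "phantom": "same-method reconstruction at the densest sampling (2048)",
    "invivo": "CS reconstruction at the acquired projection count",
}

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _pair(ref, recon) -> tuple[np.ndarray, np.ndarray]:
    a = ref.data if isinstance(ref, VolumeImage) else np.asarray(ref, dtype=float)
    b = recon.data if isinstance(recon, VolumeImage) else np.asarray(recon, dtype=float)
    if a.shape != b.shape:
        raise ValueError("reference and reconstruction shapes differ")
    if isinstance(ref, VolumeImage) and isinstance(recon, VolumeImage):
        if not ref.same_grid(recon):
            raise ValueError("reference and reconstruction grids differ")
    return a, b


def nrmse(ref, recon) -> float:
    """RMS difference over all voxels divided by the reference range."""
    a, b = _pair(ref, recon)
    rng = a.max() - a.min()
    if rng == 0:
        raise ZeroDivisionError("reference image is constant; NRMSE undefined")
    return float(np.sqrt(np.mean((a - b) ** 2)) / rng)


def mae(ref, recon) -> float:
    """Mean absolute difference of the per-image max-normalized volumes."""
    a, b = _pair(ref, recon)
    if a.max() <= 0 or b.max() <= 0:
        raise ValueError("MAE requires positive image maxima")
    return float(np.mean(np.abs(a / a.max() - b / b.max())))


def ssim(ref, recon, variant: str = "windowed", data_range: float | None = None) -> float:
    """Structural similarity between two volumes, in [-1, 1].

    ``variant="windowed"`` (default) is the mean local SSIM with Gaussian
    weighting (sigma 1.5, 11-voxel window, population covariances);
    ``variant="global"`` evaluates the SSIM formula once on whole-volume
    statistics.  ``data_range`` defaults to the dynamic range of the pair.
    """
    a, b = _pair(ref, recon)
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo
    if data_range <= 0:
        return 1.0
    if variant == "windowed":
        win = min(11, *(s if s % 2 == 1 else s - 1 for s in a.shape))
        return float(
            structural_similarity(
                a, b,
                data_range=data_range,
                gaussian_weights=True,
                sigma=1.5,
                use_sample_covariance=False,
                win_size=win,
            )
        )
    if variant == "global":
        c1 = (0.01 * data_range) ** 2
        c2 = (0.03 * data_range) ** 2
        mu_a, mu_b = a.mean(), b.mean()
        var_a, var_b = a.var(), b.var()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        return float(
            (2 * mu_a * mu_b + c1) * (2 * cov + c2)
            / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
        )
    raise ValueError("variant must be 'windowed' or 'global'")


def _rod_blur_model(x, center, width, sigma, amp, baseline):
    """Rod of ``width`` convolved with a Gaussian PSF of std ``sigma``."""
    s = max(sigma, 1e-9)
    z1 = (x - center + width / 2.0) / (s * np.sqrt(2.0))
    z2 = (x - center - width / 2.0) / (s * np.sqrt(2.0))
    return baseline + amp * 0.5 * (erf(z1) - erf(z2))


def psf_fwhm_estimate(
    profile: np.ndarray, spacing: float, structure_width: float
) -> float:
    """Gaussian PSF FWHM (mm) from a 1D profile across a known structure.

    Fits the profile as the convolution of an ideal rod of
    ``structure_width`` mm with a Gaussian and returns the Gaussian's FWHM;
    ``nan`` flags a failed fit.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 4 or profile.max() <= profile.min():
        return float("nan")
    x = np.arange(profile.size) * spacing
    amp0 = profile.max() - profile.min()
    center0 = float(x[np.argmax(profile)])
    p0 = [center0, structure_width / 4.0, amp0, profile.min()]

    def resid(p):
        center, sigma, amp, baseline = p
        return (
            _rod_blur_model(x, center, structure_width, abs(sigma), amp, baseline)
            - profile
        )

    try:
        sol = least_squares(resid, p0, method="lm", max_nfev=5000)
    except Exception:
        return float("nan")
    if not sol.success:
        return float("nan")
    sigma = abs(sol.x[1])
    return float(_FWHM_PER_SIGMA * sigma)
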