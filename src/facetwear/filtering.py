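"""Areal filtering: the S-filter, F-operator and L-filter.

A raw measured surface is decomposed into three standard stages:

* **primary** — raw surface after the S-filter, an areal Gaussian lowpass
  with cutoff ``s_cutoff_um`` that removes the smallest-scale components
  (instrument noise and unresolved microroughness);
* **S-F** — primary surface after the F-operator, a least-squares
  polynomial form removal (degree 2 by default, which absorbs tilt and
  cylinder/bowl curvature of the facet);
* **S-L** — S-F surface after the L-filter, a Gaussian highpass with
  cutoff ``l_cutoff_um`` that removes the remaining long-wavelength
  waviness.

The Gaussian weighting function is the standard areal profile-filter
kernel ``w(x, y) = 1/(a^2 lc^2) * exp(-pi (x^2 + y^2) / (a lc)^2)`` with
``a = sqrt(ln 2 / pi)``, which transmits exactly 50% of the amplitude at
the cutoff wavelength ``lc``. It is separable, so the 2D convolution is
applied as two orthogonal 1D passes with mirror padding at the borders.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d

from facetwear.surface_io import HeightMap, HeightMapError

__all__ = ["gaussian_areal_filter", "remove_form", "filter_chain",
           "DEFAULT_F_DEGREE", "DEFAULT_L_CUTOFF_UM", "default_s_cutoff_um"]

#: default L-filter (waviness) cutoff, µm: 0.025 mm, the standard nesting
#: index one class below the ~0.1 mm field size
DEFAULT_L_CUTOFF_UM = 25.0
#: default F-operator polynomial degree (handles tilt + curvature)
DEFAULT_F_DEGREE = 2

_ALPHA = np.sqrt(np.log(2.0) / np.pi)


def default_s_cutoff_um(hm: HeightMap) -> float:
    """Default S-filter (denoising) cutoff: 8 sample spacings."""
    return 8.0 * max(hm.dx, hm.dy)


def _gaussian_kernel(cutoff_um: float, spacing: float) -> np.ndarray:
    """Sampled 1D Gaussian filter kernel, normalized to unit sum.

    The kernel is truncated at +-cutoff (about 5.3 sigma), where the
    weighting function is below 6e-13 of its peak; normalization makes DC
    transmission exactly 1.
    """
    half = int(np.ceil(cutoff_um / spacing))
    x = np.arange(-half, half + 1) * spacing
    w = np.exp(-np.pi * x**2 / (_ALPHA * cutoff_um) ** 2)
    return w / w.sum()


def gaussian_areal_filter(hm: HeightMap, cutoff_um: float,
                          mode: str = "lowpass") -> HeightMap:
    """Apply the areal Gaussian filter at cutoff wavelength *cutoff_um*.

    ``lowpass`` returns the smoothed surface (amplitude transmission 50%
    at the cutoff wavelength); ``highpass`` returns input minus lowpass,
    so the two modes are exactly complementary. Borders are mirror-padded.

    The surface must be fully measured (fill voids first).
    """
    if mode not in {"lowpass", "highpass"}:
        raise ValueError(f"unknown mode {mode!r}")
    if cutoff_um <= 2.0 * max(hm.dx, hm.dy):
        raise ValueError(
            f"cutoff {cutoff_um} µm below the resolvable wavelength "
            f"{2 * max(hm.dx, hm.dy)} µm")
    if not hm.mask.all():
        raise HeightMapError("masked points present; fill_nonmeasured first")
    kx = _gaussian_kernel(cutoff_um, hm.dx)
    ky = _gaussian_kernel(cutoff_um, hm.dy)
    low = convolve1d(hm.heights, ky, axis=0, mode="mirror")
    low = convolve1d(low, kx, axis=1, mode="mirror")
    out = low if mode == "lowpass" else hm.heights - low
    res = hm.copy()
    res.heights = out
    return res


def _poly_design(hm: HeightMap, degree: int) -> np.ndarray:
    """Bivariate polynomial design matrix (total degree), on [-1, 1] coords."""
    xs = hm.x_coords()
    ys = hm.y_coords()
    # centre and scale for conditioning
    xn = (xs - xs.mean()) / max(xs.max() - xs.min(), 1.0) * 2
    yn = (ys - ys.mean()) / max(ys.max() - ys.min(), 1.0) * 2
    X, Y = np.meshgrid(xn, yn)
    cols = [X.ravel() ** i * Y.ravel() ** j
            for i in range(degree + 1)
            for j in range(degree + 1 - i)]
    return np.column_stack(cols)


def remove_form(hm: HeightMap, degree: int = DEFAULT_F_DEGREE) -> HeightMap:
    """F-operator: subtract the least-squares polynomial of total *degree*.

    The residual surface has zero mean (the constant term is part of the
    fitted polynomial).
    """
    ncoef = (degree + 1) * (degree + 2) // 2
    if hm.heights.size <= ncoef:
        raise HeightMapError("grid has too few points for the polynomial fit")
    if degree >= 1 and (hm.nrows < 2 or hm.ncols < 2):
        raise HeightMapError("degenerate grid for degree >= 1 form removal")
    A = _poly_design(hm, degree)
    z = hm.heights.ravel()
    coef, *_ = np.linalg.lstsq(A, z, rcond=None)
    resid = (z - A @ coef).reshape(hm.heights.shape)
    res = hm.copy()
    res.heights = resid
    return res


def filter_chain(hm_raw: HeightMap,
                 s_cutoff_um: float | None = None,
                 l_cutoff_um: float = DEFAULT_L_CUTOFF_UM,
                 f_degree: int = DEFAULT_F_DEGREE,
                 trim_border: bool = True):
    """Produce the primary, S-F and S-L surfaces from a filled raw map.

    ``primary = lowpass(raw, s_cutoff)``; ``S-F = remove_form(primary)``;
    ``S-L = highpass(S-F, l_cutoff)``. On the S-L stage a border band of
    width ``l_cutoff/2`` is cropped away (Gaussian end effects there are
    not attenuated by the mirror padding), unless ``trim_border=False``.

    Returns
    -------
    (primary, s_f, s_l) : three HeightMaps with stage labels set.
    """
    if s_cutoff_um is None:
        s_cutoff_um = default_s_cutoff_um(hm_raw)
    if not s_cutoff_um < l_cutoff_um:
        raise ValueError("require s_cutoff_um < l_cutoff_um")
    if not hm_raw.mask.all():
        raise HeightMapError("raw surface has voids; fill_nonmeasured first")

    primary = gaussian_areal_filter(hm_raw, s_cutoff_um, "lowpass")
    primary.stage = "primary"
    s_f = remove_form(primary, f_degree)
    s_f.stage = "S-F"
    s_l = gaussian_areal_filter(s_f, l_cutoff_um, "highpass")
    if trim_border:
        bx = int(round(l_cutoff_um / 2 / s_l.dx))
        by = int(round(l_cutoff_um / 2 / s_l.dy))
        if s_l.nrows - 2 * by >= 8 and s_l.ncols - 2 * bx >= 8:
            s_l = HeightMap(s_l.heights[by:s_l.nrows - by, bx:s_l.ncols - bx],
                            s_l.dx, s_l.dy, stage="S-F")
    s_l.stage = "S-L"
    return primary, s_f, s_l
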