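"""ISO 25178 areal surface texture parameters.

Computes the full parameter table used in dental surface texture analysis
on any surface stage (primary, S-F, S-L): height parameters (Sa, Sq, Ssk,
Sku, Sp, Sv, Sz), spatial parameters (Sal, Str, Std), hybrid parameters
(Sdq, Sdr), functional parameters from the areal material ratio
(Abbott-Firestone) curve (Smr, Smc, Sxp, Vm, Vv, Vmp, Vmc, Vvc, Vvv), and
feature parameters from watershed motif segmentation with Wolf-type
pruning (Spd, Spc, S10z, S5p, S5v, Sda, Sha, Sdv, Shv).

Conventions pinned here:

* heights are referenced to the least-squares mean plane before height,
  functional and feature parameters (so residual tilt does not bias the
  moments); hybrid parameters use the surface as given;
* heights at material ratio p% are type-7 quantiles of the height
  distribution (linear interpolation between order statistics);
* motifs shallower than 5% of Sz are merged into their neighbours
  (Wolf-type pruning via an h-extrema transform before watershed);
* Sda/Sha/Sdv/Shv are arithmetic means over the closed motifs;
* Std is the direction of the dominant angular power-spectrum lobe plus
  90 degrees (texture lies along, not across, the grooves), in [0, 180)
  from the x axis, ties broken toward the smaller angle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import local_minima, reconstruction
from skimage.segmentation import watershed

from facetwear.surface_io import HeightMap, HeightMapError

__all__ = [
    "TextureParameterSet",
    "SegmentationMotifs",
    "ConstantSurfaceError",
    "ConstantSurfaceWarning",
    "ALL_PARAMETERS",
    "DEFAULT_CONDITIONS",
    "height_params",
    "spatial_params",
    "hybrid_params",
    "functional_params",
    "segment_motifs",
    "feature_params",
    "compute_all",
]

ALL_PARAMETERS = (
    "Sa", "Sq", "Ssk", "Sku", "Sp", "Sv", "Sz",
    "Sal", "Str", "Std",
    "Sdq", "Sdr",
    "Smr", "Smc", "Sxp", "Vm", "Vv", "Vmp", "Vmc", "Vvc", "Vvv",
    "Spd", "Spc", "S10z", "S5p", "S5v", "Sda", "Sha", "Sdv", "Shv",
)

#: fixed condition constants of the parameter table
DEFAULT_CONDITIONS = {
    "Sal_s": 0.2,          # autocorrelation decay threshold
    "Str_s": 0.2,
    "Smr_c_um": 1.0,       # reference height: 1 µm under the highest peak
    "Smc_p": 10.0,         # material ratio, %
    "Sxp_p": 50.0,
    "Sxp_q": 97.5,
    "Vm_p": 10.0,
    "Vv_p": 10.0,
    "Vmp_p": 10.0,
    "Vmc_p": 10.0,
    "Vmc_q": 80.0,
    "Vvc_p": 10.0,
    "Vvc_q": 80.0,
    "Vvv_p": 80.0,
    "pruning_fraction": 0.05,   # Wolf-pruning threshold, fraction of Sz
}


class ConstantSurfaceError(HeightMapError):
    """Raised where a parameter is undefined on a constant surface."""


class ConstantSurfaceWarning(UserWarning):
    """Signals parameters that are undefined on a (near-)constant surface."""


@dataclass
class TextureParameterSet:
    """Named texture parameter values with their conditions, per stage."""

    stage: str
    values: dict = field(default_factory=dict)
    conditions: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]

    def update(self, other: dict, flags: dict | None = None):
        self.values.update(other)
        if flags:
            self.flags.update(flags)


@dataclass
class SegmentationMotifs:
    """Watershed motifs: closed dales and hills after Wolf-type pruning.

    ``dales``/``hills`` are structured record dicts with per-motif area
    (µm²), volume (µm³, relative to the pour-over saddle), extreme height
    (µm, mean-plane referenced) and the grid index of the extremum.
    """

    dales: list
    hills: list
    pruning_height_um: float
    evaluated_area_um2: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _require_filled(hm: HeightMap):
    if not hm.mask.all():
        raise HeightMapError("surface has non-measured points; fill first")


def mean_plane_residual(hm: HeightMap) -> np.ndarray:
    """Heights referenced to the least-squares mean plane (µm)."""
    if np.ptp(hm.heights) == 0.0:
        return np.zeros_like(hm.heights)
    xs = hm.x_coords()
    ys = hm.y_coords()
    X, Y = np.meshgrid(xs - xs.mean(), ys - ys.mean())
    A = np.column_stack([np.ones(X.size), X.ravel(), Y.ravel()])
    coef, *_ = np.linalg.lstsq(A, hm.heights.ravel(), rcond=None)
    return (hm.heights.ravel() - A @ coef).reshape(hm.heights.shape)


# ---------------------------------------------------------------------------
# height parameters
# ---------------------------------------------------------------------------

def height_params(hm: HeightMap) -> dict:
    """Sa, Sq, Ssk, Sku, Sp, Sv, Sz on the mean-plane-referenced surface.

    On a constant surface the amplitude parameters are zero and Ssk/Sku
    are undefined: they are returned as NaN with a
    :class:`ConstantSurfaceWarning`.
    """
    _require_filled(hm)
    z = mean_plane_residual(hm)
    sq = float(np.sqrt(np.mean(z**2)))
    out = {
        "Sa": float(np.mean(np.abs(z))),
        "Sq": sq,
        "Sp": float(z.max()),
        "Sv": float(-z.min()),
    }
    out["Sz"] = out["Sp"] + out["Sv"]
    if sq == 0.0:
        warnings.warn("constant surface: Ssk and Sku are undefined",
                      ConstantSurfaceWarning, stacklevel=2)
        out["Ssk"] = float("nan")
        out["Sku"] = float("nan")
    else:
        out["Ssk"] = float(np.mean(z**3) / sq**3)
        out["Sku"] = float(np.mean(z**4) / sq**4)
    return out


# ---------------------------------------------------------------------------
# spatial parameters
# ---------------------------------------------------------------------------

def _areal_autocorrelation(z: np.ndarray):
    """Unbiased normalized areal ACF, centred (lag 0 in the middle)."""
    n, m = z.shape
    zc = z - z.mean()
    F = np.fft.rfft2(zc, s=(2 * n, 2 * m))
    acf = np.fft.irfft2(np.abs(F) ** 2, s=(2 * n, 2 * m))
    ones = np.fft.rfft2(np.ones_like(zc), s=(2 * n, 2 * m))
    counts = np.fft.irfft2(np.abs(ones) ** 2, s=(2 * n, 2 * m))
    counts = np.maximum(counts, 1e-9)
    acf = acf / counts
    # reorder so lag (0, 0) sits at index (n-1, m-1)
    acf = np.roll(acf, (n - 1, m - 1), axis=(0, 1))[: 2 * n - 1, : 2 * m - 1]
    return acf / acf[n - 1, m - 1]


def spatial_params(hm: HeightMap, s: float = 0.2, n_angles: int = 180) -> dict:
    """Sal, Str (decay threshold *s*) and Std (texture direction, deg).

    Sal is the shortest distance over all directions at which the
    normalized areal autocorrelation decays to <= s; Str is that shortest
    distance divided by the longest. Directions along which the ACF never
    decays within half the field are capped there and flagged via the
    ``Str_flag``/``Sal_flag`` entries of the returned dict (popped into
    the flag set by :func:`compute_all`).
    """
    _require_filled(hm)
    if not 0 < s < 1:
        raise ValueError("s must be in (0, 1)")
    z = mean_plane_residual(hm)
    n, m = z.shape
    acf = _areal_autocorrelation(z)
    c0 = (n - 1, m - 1)
    rmax = min((n - 1) * hm.dy, (m - 1) * hm.dx) / 2.0
    dr = min(hm.dx, hm.dy) / 2.0
    radii = np.arange(0.0, rmax + dr, dr)
    angles = np.deg2rad(np.arange(n_angles) * 180.0 / n_angles)
    # both the ray at theta and theta+pi (ACF is symmetric, either works)
    rows = c0[0] + np.outer(np.sin(angles), radii) / hm.dy
    cols = c0[1] + np.outer(np.cos(angles), radii) / hm.dx
    prof = ndimage.map_coordinates(acf, [rows, cols], order=1, mode="nearest")

    below = prof <= s
    decay = np.full(len(angles), np.nan)
    for i in range(len(angles)):
        idx = np.argmax(below[i])
        if below[i, idx]:
            if idx == 0:
                decay[i] = 0.0
            else:
                a0, a1 = prof[i, idx - 1], prof[i, idx]
                frac = (a0 - s) / (a0 - a1) if a1 != a0 else 1.0
                decay[i] = radii[idx - 1] + frac * dr
    flags = {}
    if np.isnan(decay).all():
        raise HeightMapError(
            "autocorrelation never decays below s within the field")
    if np.isnan(decay).any():
        flags["Str"] = "acf did not decay in some directions; capped at rmax"
        decay = np.where(np.isnan(decay), rmax, decay)
    sal = float(decay.min())
    smax = float(decay.max())
    out = {"Sal": sal, "Str": sal / smax if smax > 0 else 1.0,
           "Std": _texture_direction(z, hm.dx, hm.dy)}
    if flags:
        out["_flags"] = flags
    return out


def _texture_direction(z: np.ndarray, dx: float, dy: float,
                       bin_deg: float = 1.0) -> float:
    """Dominant texture direction from the angular power spectrum."""
    n, m = z.shape
    F = np.fft.fft2(z - z.mean())
    P = np.abs(F) ** 2
    fy = np.fft.fftfreq(n, d=dy)
    fx = np.fft.fftfreq(m, d=dx)
    FX, FY = np.meshgrid(fx, fy)
    P[0, 0] = 0.0                       # drop DC
    ang = np.rad2deg(np.arctan2(FY, FX)) % 180.0
    nbins = int(round(180.0 / bin_deg))
    bins = (ang / bin_deg).astype(int) % nbins
    power = np.bincount(bins.ravel(), weights=P.ravel(), minlength=nbins)
    k = int(np.argmax(power))           # first max -> smaller angle on ties
    # parabolic interpolation over the circular neighbourhood
    pm, p0, pp = power[(k - 1) % nbins], power[k], power[(k + 1) % nbins]
    denom = pm - 2 * p0 + pp
    shift = 0.0 if denom == 0 else 0.5 * (pm - pp) / denom
    spec_angle = (k + shift) * bin_deg
    return float((spec_angle + 90.0) % 180.0)


# ---------------------------------------------------------------------------
# hybrid parameters
# ---------------------------------------------------------------------------

def hybrid_params(hm: HeightMap) -> dict:
    """Sdq (RMS gradient) and Sdr (developed interfacial area ratio, %)."""
    _require_filled(hm)
    gy, gx = np.gradient(hm.heights, hm.dy, hm.dx)
    g2 = gx**2 + gy**2
    return {
        "Sdq": float(np.sqrt(np.mean(g2))),
        "Sdr": float((np.mean(np.sqrt(1.0 + g2)) - 1.0) * 100.0),
    }


# ---------------------------------------------------------------------------
# functional parameters (areal material ratio curve)
# ---------------------------------------------------------------------------

def _height_at_mr(z: np.ndarray, p: float) -> float:
    """Height (µm) at material ratio p% — the type-7 (1 - p/100) quantile."""
    return float(np.quantile(z, 1.0 - p / 100.0, method="linear"))


def functional_params(hm: HeightMap, conditions: dict | None = None) -> dict:
    """Smr, Smc, Sxp and the five volume parameters, per projected area.

    All values derive from the empirical areal material ratio curve: the
    monotone non-increasing map from height to the percentage of material
    at or above that height. Volumes are integrals of material (void)
    above (below) the heights at the stated ratios, in µm³/µm².
    """
    _require_filled(hm)
    cond = dict(DEFAULT_CONDITIONS)
    if conditions:
        cond.update(conditions)
    z = mean_plane_residual(hm).ravel()

    def vm(p):
        h = _height_at_mr(z, p)
        return float(np.mean(np.clip(z - h, 0.0, None)))

    def vv(p):
        h = _height_at_mr(z, p)
        return float(np.mean(np.clip(h - z, 0.0, None)))

    level = z.max() - cond["Smr_c_um"]
    out = {
        "Smr": float(np.mean(z >= level) * 100.0),
        "Smc": _height_at_mr(z, cond["Smc_p"]),
        "Sxp": _height_at_mr(z, cond["Sxp_p"]) - _height_at_mr(z, cond["Sxp_q"]),
        "Vm": vm(cond["Vm_p"]),
        "Vv": vv(cond["Vv_p"]),
        "Vmp": vm(cond["Vmp_p"]),
        "Vmc": vm(cond["Vmc_q"]) - vm(cond["Vmc_p"]),
        "Vvc": vv(cond["Vvc_p"]) - vv(cond["Vvc_q"]),
        "Vvv": vv(cond["Vvv_p"]),
    }
    return out


# ---------------------------------------------------------------------------
# segmentation (motifs) and feature parameters
# ---------------------------------------------------------------------------

def _motif_records(z: np.ndarray, dx: float, dy: float, prune_h: float,
                   invert: bool) -> list:
    """Watershed motifs of -z-dales (invert=False) or hills (invert=True).

    Minima shallower than *prune_h* are merged into their neighbours by an
    h-minima reconstruction before the watershed (Wolf-type pruning). Each
    motif's volume is integrated relative to its pour-over saddle (the
    lowest point on its watershed rim).
    """
    w = -z if invert else z
    if prune_h > 0:
        w_f = reconstruction(w + prune_h, w, method="erosion")
    else:
        w_f = w
    minima = local_minima(w_f, connectivity=2)
    markers, n_mark = ndimage.label(minima)
    if n_mark == 0:
        return []
    labels = watershed(w_f, markers=markers, connectivity=1)

    # rim pixels: adjacent (4-connectivity) to a different motif
    rim = np.zeros(labels.shape, dtype=bool)
    rim[:-1, :] |= labels[:-1, :] != labels[1:, :]
    rim[1:, :] |= labels[1:, :] != labels[:-1, :]
    rim[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    rim[:, 1:] |= labels[:, 1:] != labels[:, :-1]

    ids = np.arange(1, n_mark + 1)
    w_rim = np.where(rim, w, np.inf)
    if n_mark == 1:
        # single motif: rim is the image border
        w_rim = w.copy()
        w_rim[1:-1, 1:-1] = np.inf
    pour = ndimage.minimum(w_rim, labels, index=ids)
    pour_px = pour[labels - 1]
    depth_px = np.clip(pour_px - w, 0.0, None)
    vol = ndimage.sum_labels(depth_px, labels, index=ids) * dx * dy
    area = ndimage.sum_labels(np.ones_like(w), labels, index=ids) * dx * dy
    extreme = ndimage.minimum(w, labels, index=ids)       # motif minimum of w
    argmin = ndimage.minimum_position(w, labels, index=ids)

    records = []
    for i, mid in enumerate(ids):
        rec = {
            "area_um2": float(area[i]),
            "volume_um3": float(vol[i]),
            "relief_um": float(pour[i] - extreme[i]),
            "extreme_um": float(-extreme[i]) if invert else float(extreme[i]),
            "extreme_idx": tuple(int(v) for v in argmin[i]),
        }
        records.append(rec)
    return records


def segment_motifs(hm: HeightMap, pruning_fraction: float = 0.05
                   ) -> SegmentationMotifs:
    """Watershed segmentation into closed dales and hills.

    Motifs with local relief below ``pruning_fraction * Sz`` are merged
    into their neighbours (default 5% of Sz).
    """
    _require_filled(hm)
    z = mean_plane_residual(hm)
    sz = float(z.max() - z.min())
    if sz == 0.0:
        raise ConstantSurfaceError("constant surface has no motifs")
    prune_h = pruning_fraction * sz
    dales = _motif_records(z, hm.dx, hm.dy, prune_h, invert=False)
    hills = _motif_records(z, hm.dx, hm.dy, prune_h, invert=True)
    area = hm.heights.size * hm.dx * hm.dy
    return SegmentationMotifs(dales=dales, hills=hills,
                              pruning_height_um=prune_h,
                              evaluated_area_um2=area)


def _peak_curvature(z: np.ndarray, dx: float, dy: float,
                    peaks: list) -> float:
    """Arithmetic mean of the mean principal curvature at the hill peaks,
    from local 5x5 quadric fits (1/µm). Peaks closer than 2 px to the
    border are skipped."""
    n, m = z.shape
    uu, vv = np.meshgrid(np.arange(-2, 3) * dx, np.arange(-2, 3) * dy)
    A = np.column_stack([np.ones(25), uu.ravel(), vv.ravel(),
                         uu.ravel() ** 2, (uu * vv).ravel(), vv.ravel() ** 2])
    Apinv = np.linalg.pinv(A)
    curv = []
    for (r, c) in peaks:
        if not (2 <= r < n - 2 and 2 <= c < m - 2):
            continue
        patch = z[r - 2:r + 3, c - 2:c + 3].ravel()
        coef = Apinv @ patch
        # z ~ a + bu + cv + d u^2 + e uv + f v^2; mean curvature of a peak
        # is -(z_xx + z_yy)/2 = -(d + f)
        curv.append(-(coef[3] + coef[5]))
    return float(np.mean(curv)) if curv else float("nan")


def feature_params(motifs: SegmentationMotifs, hm: HeightMap) -> dict:
    """Spd, Spc, S10z, S5p, S5v, Sda, Sha, Sdv, Shv from the motif set."""
    if not motifs.dales and not motifs.hills:
        raise HeightMapError("empty motif set")
    z = mean_plane_residual(hm)
    flags = {}

    peak_heights = sorted((h["extreme_um"] for h in motifs.hills),
                          reverse=True)
    pit_depths = sorted((-d["extreme_um"] for d in motifs.dales),
                        reverse=True)
    if len(peak_heights) < 5 or len(pit_depths) < 5:
        flags["S10z"] = "fewer than five peaks or pits; used all"
    s5p = float(np.mean(peak_heights[:5])) if peak_heights else 0.0
    s5v = float(np.mean(pit_depths[:5])) if pit_depths else 0.0

    peaks = [h["extreme_idx"] for h in motifs.hills]
    out = {
        "Spd": len(motifs.hills) / motifs.evaluated_area_um2,
        "Spc": _peak_curvature(z, hm.dx, hm.dy, peaks),
        "S5p": s5p,
        "S5v": s5v,
        "S10z": s5p + s5v,
        "Sda": float(np.mean([d["area_um2"] for d in motifs.dales])
                     ) if motifs.dales else float("nan"),
        "Sdv": float(np.mean([d["volume_um3"] for d in motifs.dales])
                     ) if motifs.dales else float("nan"),
        "Sha": float(np.mean([h["area_um2"] for h in motifs.hills])
                     ) if motifs.hills else float("nan"),
        "Shv": float(np.mean([h["volume_um3"] for h in motifs.hills])
                     ) if motifs.hills else float("nan"),
    }
    if flags:
        out["_flags"] = flags
    return out


# ---------------------------------------------------------------------------
# everything
# ---------------------------------------------------------------------------

def compute_all(hm: HeightMap, conditions: dict | None = None,
                pruning_fraction: float | None = None) -> TextureParameterSet:
    """Compute the full texture parameter table on one surface stage.

    Identical input gives bit-identical output (every step is
    deterministic).
    """
    cond = dict(DEFAULT_CONDITIONS)
    if conditions:
        cond.update(conditions)
    if pruning_fraction is not None:
        cond["pruning_fraction"] = pruning_fraction
    ps = TextureParameterSet(stage=hm.stage, conditions=cond)

    ps.update(height_params(hm))
    sp = spatial_params(hm, s=cond["Sal_s"])
    ps.update(sp, flags=sp.pop("_flags", None))
    ps.update(hybrid_params(hm))
    ps.update(functional_params(hm, cond))
    motifs = segment_motifs(hm, cond["pruning_fraction"])
    fp = feature_params(motifs, hm)
    ps.update(fp, flags=fp.pop("_flags", None))
    ps.values = {k: ps.values[k] for k in ALL_PARAMETERS}
    return ps
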