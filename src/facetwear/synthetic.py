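"""Synthetic occlusal-facet surfaces for the four-diet rabbit experiment.

The feeding experiment compares four pelleted diets — grass meal (G),
grass meal + oats (GO), lucerne + oats (LO) and lucerne (L) — whose silica
content spans 11.96 mg/g dry matter (G) down to 0.10 mg/g (L). Because the
original confocal scans were never deposited, this module generates
surrogate data with the group structure the experiment reports:

* high-silica diets cut more, longer, better-aligned scratches;
* low-silica diets leave more pits and a finer accumulated micro-relief
  (the low wear rate "overwrites" old texture more slowly), which also
  makes animals on those diets more variable among each other.

Every animal yields (a) a 160x160 µm, 512x512-point 3D height map — a
quadratic facet form, two waviness sinusoids, rendered wear features,
instrument noise and a non-measured dropout mask — with its exact
ground-truth feature list, and (b) an independent 2D feature field for the
300x300 µm microwear counting square (the two methods image the facet at
different magnifications, so they are modelled as two draws of the same
per-animal stochastic process).

Group rate parameters are tied to dietary silica by affine-in-log(SC)
coupling, anchored so that expected group means of the pit count Np and
mean scratch length Ls equal the reported values 21.7 (G) / 45.9 (L) and
59.1 µm (G) / 38.9 µm (L).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from facetwear.surface_io import HeightMap

__all__ = [
    "DietGroupConfig",
    "SurfaceFeature",
    "AnimalSample",
    "default_group_configs",
    "render_feature",
    "generate_surface",
    "generate_counting_features",
    "generate_group_sample",
]

#: pit/scratch aspect-ratio threshold shared with the microwear module
PIT_SCRATCH_ASPECT = 4.0

#: default 3D field: 160x160 µm at 512x512 points
DEFAULT_EXTENT_UM = 160.0
DEFAULT_N_POINTS = 512
#: microwear counting square side (µm); features are drawn on a slightly
#: larger region so border features can fall in or out of the square
COUNTING_SQUARE_UM = 300.0
_FIELD_MARGIN = 1.2

#: instrument white-noise standard deviation (µm) and dropout fraction
DEFAULT_NOISE_SD_UM = 0.05
DEFAULT_DROPOUT = 0.05

#: printed anchor values for the silica -> wear-rate coupling
_SILICA_G = 11.96   # mg/g DM, grass
_SILICA_L = 0.10    # mg/g DM, lucerne
_NP_G, _NP_L = 21.7, 45.9      # mean pit counts per counting square
_LS_G, _LS_L = 59.1, 38.9      # mean scratch length, µm


@dataclass
class SurfaceFeature:
    """One wear feature: an elliptical-Gaussian depression.

    ``length_um``/``width_um`` are the major/minor axis extents, the
    depression's visible footprint; ``orientation_deg`` is the major-axis
    direction in [0, 180) from the x axis.
    """

    kind: str                    # "pit" | "scratch"
    center_x: float
    center_y: float
    length_um: float
    width_um: float
    depth_um: float
    orientation_deg: float

    def __post_init__(self):
        if not (self.length_um >= self.width_um > 0):
            raise ValueError("require length_um >= width_um > 0")
        if self.depth_um <= 0:
            raise ValueError("depth_um must be positive")
        self.orientation_deg = float(self.orientation_deg) % 180.0
        if self.kind not in {"pit", "scratch"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if (self.kind == "pit"
                and self.length_um / self.width_um >= PIT_SCRATCH_ASPECT):
            raise ValueError("pit aspect ratio exceeds the pit/scratch threshold")

    @property
    def aspect(self) -> float:
        return self.length_um / self.width_um


@dataclass
class DietGroupConfig:
    """Stochastic wear model for one diet group.

    Rates are expected feature counts per 300x300 µm counting square;
    ``micro_relief_rate`` is the expected count of sub-optical plateau/
    dimple micro-features per 160x160 µm 3D field (not visible to the 2D
    counting method). ``between_animal_cv`` scales a per-animal gamma
    multiplier applied to all rates and to the depth scale.
    """

    label: str
    n_animals: int
    silica_mg_g: float
    scratch_rate: float
    pit_rate: float
    orientation_kappa: float
    depth_scale_um: float
    between_animal_cv: float
    target_Np: float
    target_Ls_um: float
    micro_relief_rate: float = 0.0
    preferred_orientation_deg: float = 30.0
    extent_um: float = DEFAULT_EXTENT_UM
    n_points: int = DEFAULT_N_POINTS
    noise_sd_um: float = DEFAULT_NOISE_SD_UM
    dropout_fraction: float = DEFAULT_DROPOUT

    def __post_init__(self):
        if self.silica_mg_g < 0:
            raise ValueError("silica_mg_g must be >= 0")
        for name in ("scratch_rate", "pit_rate", "orientation_kappa",
                     "between_animal_cv", "micro_relief_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.dropout_fraction < 0.20:
            raise ValueError("dropout_fraction must stay below the 20% ceiling")


def _log_interp(sc: float, v_g: float, v_l: float) -> float:
    """Affine-in-log(silica) interpolation between the G and L anchors."""
    t = (np.log(sc) - np.log(_SILICA_L)) / (np.log(_SILICA_G) - np.log(_SILICA_L))
    return float(v_l + t * (v_g - v_l))


def default_group_configs() -> list[DietGroupConfig]:
    """The four diet groups of the experiment (G, GO, LO, L; n = 7,6,7,6).

    Silica anchors are the printed extremes; the oats-containing
    intermediate diets are placed at 2.5 (GO) and 1.2 (LO) mg/g DM. Pit
    rate, scratch rate, scratch length, orientation concentration,
    between-animal CV, depth scale and micro-relief rate all follow the
    affine-in-log(silica) coupling, so that higher silica means more and
    longer, better-aligned scratches, fewer pits, less accumulated
    micro-relief and lower between-animal variability.
    """
    silica = {"G": _SILICA_G, "GO": 1.65, "LO": 1.3, "L": _SILICA_L}
    n = {"G": 7, "GO": 6, "LO": 7, "L": 6}
    configs = []
    for label in ("G", "GO", "LO", "L"):
        sc = silica[label]
        configs.append(DietGroupConfig(
            label=label,
            n_animals=n[label],
            silica_mg_g=sc,
            scratch_rate=_log_interp(sc, 30.0, 8.0),
            pit_rate=_log_interp(sc, _NP_G, _NP_L),
            orientation_kappa=_log_interp(sc, 8.0, 0.8),
            depth_scale_um=_log_interp(sc, 1.2, 2.0),
            between_animal_cv=_log_interp(sc, 0.12, 0.45),
            target_Np=_log_interp(sc, _NP_G, _NP_L),
            target_Ls_um=_log_interp(sc, _LS_G, _LS_L),
            micro_relief_rate=_log_interp(sc, 5.0, 40.0),
        ))
    return configs


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_feature(feature: SurfaceFeature, hm: HeightMap) -> HeightMap:
    """Subtract the feature's elliptical-Gaussian depression from *hm*.

    The profile is ``depth * exp(-2 ((u/a)^2 + (v/b)^2))`` in the rotated
    frame with semi-axes ``a = length/2``, ``b = width/2``; it is rendered
    inside a window of 3 axis-lengths and exactly zero outside, so
    rendering disjoint features commutes.
    """
    out = hm.copy()
    _render_into(out.heights, feature, hm.dx, hm.dy)
    return out


def _render_into(z: np.ndarray, f: SurfaceFeature, dx: float, dy: float,
                 sign: float = -1.0) -> None:
    nrows, ncols = z.shape
    ex, ey = (ncols - 1) * dx, (nrows - 1) * dy
    if not (0 <= f.center_x <= ex and 0 <= f.center_y <= ey):
        raise ValueError("feature centre outside the grid extent")
    a = f.length_um / 2.0
    b = f.width_um / 2.0
    r = 3.0 * f.length_um          # window half-size: 3 axis-lengths
    c0 = max(int(np.floor((f.center_x - r) / dx)), 0)
    c1 = min(int(np.ceil((f.center_x + r) / dx)) + 1, ncols)
    r0 = max(int(np.floor((f.center_y - r) / dy)), 0)
    r1 = min(int(np.ceil((f.center_y + r) / dy)) + 1, nrows)
    xs = np.arange(c0, c1) * dx - f.center_x
    ys = np.arange(r0, r1) * dy - f.center_y
    X, Y = np.meshgrid(xs, ys)
    th = np.deg2rad(f.orientation_deg)
    u = X * np.cos(th) + Y * np.sin(th)
    v = -X * np.sin(th) + Y * np.cos(th)
    z[r0:r1, c0:c1] += sign * f.depth_um * np.exp(
        -2.0 * ((u / a) ** 2 + (v / b) ** 2))


# ---------------------------------------------------------------------------
# stochastic draws
# ---------------------------------------------------------------------------

def _animal_streams(config: DietGroupConfig, animal_index: int, seed: int):
    """Three deterministic per-animal streams: base (animal-level draws),
    3D surface, and 2D counting field. Keeping the surface and the
    counting field on separate child streams makes ``generate_surface``
    and ``generate_counting_features`` agree with ``generate_group_sample``
    draw for draw."""
    ss = np.random.SeedSequence(
        [int(seed) % 2**31, zlib.crc32(config.label.encode()), int(animal_index)])
    child_surf, child_count = ss.spawn(2)
    return (np.random.default_rng(ss),
            np.random.default_rng(child_surf),
            np.random.default_rng(child_count))


def _rate_multiplier(rng, cv: float) -> float:
    """Gamma-distributed per-animal multiplier with mean 1 and CV *cv*."""
    if cv <= 0:
        return 1.0
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, cv**2))


def _axial_orientation(rng, kappa: float, mu_deg: float) -> float:
    """Axial von Mises draw mapped to [0, 180) degrees."""
    if kappa <= 0:
        return float(rng.uniform(0.0, 180.0))
    theta = rng.vonmises(np.deg2rad(2.0 * mu_deg), kappa)
    return float(np.rad2deg(theta) / 2.0) % 180.0

def _lognormal_with_mean(rng, mean: float, sigma_log: float) -> float:
    """Log-normal draw with the given arithmetic mean."""
    mu = np.log(mean) - sigma_log**2 / 2.0
    return float(rng.lognormal(mu, sigma_log))


def _draw_scratch(rng, config: DietGroupConfig, ex: float, ey: float,
                  depth_scale: float) -> SurfaceFeature:
    length = _lognormal_with_mean(rng, config.target_Ls_um, 0.30)
    width = _lognormal_with_mean(rng, 3.5, 0.30)
    width = min(width, length / PIT_SCRATCH_ASPECT)  # keep it a scratch
    depth = _lognormal_with_mean(rng, 0.6 * depth_scale, 0.35)
    return SurfaceFeature(
        kind="scratch",
        center_x=float(rng.uniform(0, ex)), center_y=float(rng.uniform(0, ey)),
        length_um=length, width_um=width, depth_um=depth,
        orientation_deg=_axial_orientation(
            rng, config.orientation_kappa, config.preferred_orientation_deg),
    )


def _draw_pit(rng, config: DietGroupConfig, ex: float, ey: float,
              depth_scale: float, diameter_um: float = 8.0,
              sigma_log: float = 0.45) -> SurfaceFeature:
    diam = _lognormal_with_mean(rng, diameter_um, sigma_log)
    aspect = float(rng.uniform(1.0, 2.2))
    depth = _lognormal_with_mean(rng, depth_scale, 0.35)
    return SurfaceFeature(
        kind="pit",
        center_x=float(rng.uniform(0, ex)), center_y=float(rng.uniform(0, ey)),
        length_um=diam * np.sqrt(aspect), width_um=diam / np.sqrt(aspect),
        depth_um=depth,
        orientation_deg=float(rng.uniform(0.0, 180.0)),
    )


def _surface_feature_counts(rng, config: DietGroupConfig, mult: float):
    # 3D field rates scale with the area ratio of the two imaged regions
    area_scale = (config.extent_um / COUNTING_SQUARE_UM) ** 2
    n_scratch = rng.poisson(config.scratch_rate * mult * area_scale)
    n_pit = rng.poisson(config.pit_rate * mult * area_scale)
    n_micro = rng.poisson(config.micro_relief_rate * mult)
    return int(n_scratch), int(n_pit), int(n_micro)


def generate_surface(config: DietGroupConfig, animal_index: int, seed: int):
    """Generate one animal's 3D height map and ground-truth feature list.

    The surface is quadratic facet form + two waviness sinusoids + rendered
    wear features + accumulated micro-relief (paired shallow dimples and
    plateau bumps, modelling texture that low wear rates fail to overwrite)
    + white instrument noise, with a random non-measured dropout mask. The
    same (config, animal_index, seed) reproduces the output bit-exactly.
    """
    base, rng_surf, _ = _animal_streams(config, animal_index, seed)
    mult = _rate_multiplier(base, config.between_animal_cv)
    return _generate_surface_with(rng_surf, config, mult)


def _generate_surface_with(rng, config: DietGroupConfig, mult: float):
    npts = config.n_points
    ex = ey = config.extent_um
    dx = dy = ex / (npts - 1)
    x = np.arange(npts) * dx
    y = np.arange(npts) * dy
    X, Y = np.meshgrid(x, y)

    # facet form: a quadratic bowl, ~4 µm of sag over the field
    u = (X - ex / 2) / (ex / 2)
    v = (Y - ey / 2) / (ey / 2)
    z = -2.0 * (u**2 + v**2)

    # waviness: two low-frequency sinusoids with random phases
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    z += 0.5 * np.sin(2 * np.pi * X / 60.0 + ph1)
    z += 0.4 * np.sin(2 * np.pi * (0.3 * X + 0.7 * Y) / 90.0 + ph2)

    depth_scale = config.depth_scale_um * (mult ** 0.5)
    n_scratch, n_pit, n_micro = _surface_feature_counts(rng, config, mult)
    features: list[SurfaceFeature] = []
    for _ in range(n_scratch):
        features.append(_draw_scratch(rng, config, ex, ey, depth_scale))
    for _ in range(n_pit):
        features.append(_draw_pit(rng, config, ex, ey, depth_scale))
    for f in features:
        _render_into(z, f, dx, dy)

    # accumulated micro-relief: shallow dimple/plateau pairs, not part of
    # the optically countable ground truth; their relief scales with the
    # group depth scale (and the animal's wear multiplier), so groups with
    # deep, infrequent wear also carry taller residual plateaus
    for _ in range(n_micro):
        diam = _lognormal_with_mean(rng, 5.0, 0.40)
        aspect = float(rng.uniform(1.0, 1.8))
        height = _lognormal_with_mean(rng, 0.3 * depth_scale, 0.40)
        mf = SurfaceFeature(
            kind="pit",
            center_x=float(rng.uniform(0, ex)), center_y=float(rng.uniform(0, ey)),
            length_um=diam * np.sqrt(aspect), width_um=diam / np.sqrt(aspect),
            depth_um=height, orientation_deg=float(rng.uniform(0, 180.0)),
        )
        _render_into(z, mf, dx, dy, sign=-1.0 if rng.random() < 0.5 else 1.0)

    if config.noise_sd_um > 0:
        z = z + rng.normal(0.0, config.noise_sd_um, size=z.shape)

    mask = np.ones_like(z, dtype=bool)
    if config.dropout_fraction > 0:
        mask = rng.random(z.shape) >= config.dropout_fraction
    zm = np.where(mask, z, np.nan)
    hm = HeightMap(zm, dx=dx, dy=dy, mask=mask, stage="raw")
    return hm, features


def generate_counting_features(config: DietGroupConfig, animal_index: int,
                               seed: int) -> list[SurfaceFeature]:
    """Feature field for the 300x300 µm microwear counting square.

    Features are drawn on a 1.2x larger region centred on the square so
    the centre-in-square counting rule sees realistic edge traffic; the
    expected in-square pit and scratch counts equal the config rates
    (times the animal's rate multiplier).
    """
    base, _, rng_count = _animal_streams(config, animal_index, seed)
    mult = _rate_multiplier(base, config.between_animal_cv)
    return _generate_counting_with(rng_count, config, mult)


def _generate_counting_with(rng, config: DietGroupConfig,
                            mult: float) -> list[SurfaceFeature]:
    side = COUNTING_SQUARE_UM * _FIELD_MARGIN
    area_scale = _FIELD_MARGIN ** 2
    depth_scale = config.depth_scale_um * (mult ** 0.5)
    n_scratch = rng.poisson(config.scratch_rate * mult * area_scale)
    n_pit = rng.poisson(config.pit_rate * mult * area_scale)
    feats = []
    for _ in range(int(n_scratch)):
        feats.append(_draw_scratch(rng, config, side, side, depth_scale))
    for _ in range(int(n_pit)):
        feats.append(_draw_pit(rng, config, side, side, depth_scale))
    return feats


@dataclass
class AnimalSample:
    """One animal of the experiment bundle."""

    animal_id: str
    group: str
    silica_mg_g: float          # per-animal assay value of the feed batch
    surface: HeightMap          # raw 3D height map (with dropout mask)
    features_3d: list = field(default_factory=list)
    features_2d: list = field(default_factory=list)
    seed_key: tuple = ()


def generate_group_sample(configs: list[DietGroupConfig] | None = None,
                          master_seed: int = 0) -> list[AnimalSample]:
    """Generate the full experiment bundle (default 7+6+7+6 = 26 animals).

    Per-animal seeds derive deterministically from ``master_seed`` and the
    group label, so the whole bundle is reproducible. The per-animal silica
    covariate is the group feed value with a 5% CV log-normal assay jitter.
    """
    if configs is None:
        configs = default_group_configs()
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    bundle = []
    for config in configs:
        for i in range(config.n_animals):
            base, rng_surf, rng_count = _animal_streams(config, i, master_seed)
            mult = _rate_multiplier(base, config.between_animal_cv)
            hm, feats3d = _generate_surface_with(rng_surf, config, mult)
            feats2d = _generate_counting_with(rng_count, config, mult)
            silica = config.silica_mg_g * float(
                base.lognormal(-0.05**2 / 2.0, 0.05))
            bundle.append(AnimalSample(
                animal_id=f"{config.label}{i + 1}",
                group=config.label,
                silica_mg_g=silica,
                surface=hm,
                features_3d=feats3d,
                features_2d=feats2d,
                seed_key=(master_seed, config.label, i),
            ))
    return bundle
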