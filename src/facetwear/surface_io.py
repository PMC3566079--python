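"""Gridded height-map container and I/O.

Surfaces are regular rectangular grids of heights in µm with a per-point
measured/non-measured mask, as produced by confocal disc-scanning
profilometry. Two plain-text containers are supported:

``csv-grid``
    A comma-separated matrix (one row per y line) preceded by comment
    headers ``# dx=<µm> dy=<µm> unit=um stage=<stage> precision=17g``.
    Non-measured points are written as the token ``NaN``. Heights are
    serialized with 17 significant digits, so a read/write round trip is
    bit-exact.

``x3p-like``
    A minimal zipped-XML record holding the grid dimensions, lateral
    spacings and a whitespace-separated height list; modelled on the
    ISO 5436-2 x3p layout without claiming conformance.

Coordinate convention: x runs along columns, y along rows, origin at the
grid's lower-left corner; heights are positive upward.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lxml import etree

__all__ = [
    "HeightMap",
    "HeightMapError",
    "read_height_map",
    "write_height_map",
    "validate_measured_fraction",
    "fill_nonmeasured",
]

#: allowed processing stages, in pipeline order
STAGES = ("raw", "primary", "S-F", "S-L")

#: legal stage transitions (raw -> primary -> {S-F, S-L})
_STAGE_SUCCESSORS = {
    "raw": {"primary"},
    "primary": {"S-F"},
    "S-F": {"S-L"},
    "S-L": set(),
}


class HeightMapError(ValueError):
    """Raised on malformed height-map files or invalid grid operations."""


@dataclass
class HeightMap:
    """A gridded surface: heights (µm) on a regular (dy, dx) lattice.

    Parameters
    ----------
    heights : (nrows, ncols) float array
        Surface heights in µm. Values at non-measured points are ignored
        (they are NaN after reading).
    dx, dy : float
        Lateral sample spacing in µm along columns (x) and rows (y).
    mask : (nrows, ncols) bool array
        True where the point was measured.
    stage : str
        One of ``raw``, ``primary``, ``S-F``, ``S-L``.
    """

    heights: np.ndarray
    dx: float
    dy: float
    mask: np.ndarray = None
    stage: str = "raw"

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise HeightMapError("heights must be a 2D grid")
        if self.dx <= 0 or self.dy <= 0:
            raise HeightMapError("dx and dy must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.heights)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.heights.shape:
            raise HeightMapError("mask shape must match heights shape")
        if self.stage not in STAGES:
            raise HeightMapError(f"unknown stage {self.stage!r}")
        if not np.all(np.isfinite(self.heights[self.mask])):
            raise HeightMapError("non-finite height at a measured point")

    @property
    def nrows(self) -> int:
        return self.heights.shape[0]

    @property
    def ncols(self) -> int:
        return self.heights.shape[1]

    @property
    def extent_x(self) -> float:
        """Physical size along x in µm, (ncols-1)*dx."""
        return (self.ncols - 1) * self.dx

    @property
    def extent_y(self) -> float:
        """Physical size along y in µm, (nrows-1)*dy."""
        return (self.nrows - 1) * self.dy

    @property
    def measured_fraction(self) -> float:
        return float(self.mask.mean())

    def x_coords(self) -> np.ndarray:
        return np.arange(self.ncols) * self.dx

    def y_coords(self) -> np.ndarray:
        return np.arange(self.nrows) * self.dy

    def with_heights(self, heights: np.ndarray, stage: str | None = None) -> "HeightMap":
        """Copy with new heights (and optionally a new stage label)."""
        new_stage = self.stage if stage is None else stage
        if stage is not None and stage != self.stage:
            if stage not in _STAGE_SUCCESSORS.get(self.stage, set()):
                raise HeightMapError(
                    f"illegal stage transition {self.stage!r} -> {stage!r}"
                )
        return HeightMap(
            heights=np.array(heights, dtype=float),
            dx=self.dx,
            dy=self.dy,
            mask=self.mask.copy(),
            stage=new_stage,
        )

    def copy(self) -> "HeightMap":
        return HeightMap(self.heights.copy(), self.dx, self.dy,
                         self.mask.copy(), self.stage)


# ---------------------------------------------------------------------------
# csv-grid dialect
# ---------------------------------------------------------------------------

def _write_csv_grid(hm: HeightMap, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# dx={hm.dx!r} dy={hm.dy!r} unit=um stage={hm.stage} "
                 f"precision=17g\n")
        z = np.where(hm.mask, hm.heights, np.nan)
        for row in z:
            fh.write(",".join("NaN" if not np.isfinite(v) else f"{v:.17g}"
                              for v in row))
            fh.write("\n")


def _read_csv_grid(path: Path) -> HeightMap:
    dx = dy = None
    stage = "raw"
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("dx="):
                        dx = float(token[3:])
                    elif token.startswith("dy="):
                        dy = float(token[3:])
                    elif token.startswith("stage="):
                        stage = token[6:]
                continue
            tokens = line.split(",")
            try:
                row = [float("nan") if t.strip().lower() == "nan"
                       else float(t) for t in tokens]
            except ValueError as exc:
                raise HeightMapError(
                    f"{path}:{lineno}: unparseable token") from exc
            rows.append(row)
    if dx is None or dy is None:
        raise HeightMapError(f"{path}: missing dx/dy spacing metadata")
    if not rows:
        raise HeightMapError(f"{path}: empty grid")
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise HeightMapError(f"{path}: ragged rows")
    heights = np.array(rows, dtype=float)
    mask = np.isfinite(heights)
    if not mask.any():
        raise HeightMapError(f"{path}: all points are non-measured")
    return HeightMap(heights, dx=dx, dy=dy, mask=mask, stage=stage)


# ---------------------------------------------------------------------------
# x3p-like zipped XML
# ---------------------------------------------------------------------------

def _write_x3p_like(hm: HeightMap, path: Path) -> None:
    root = etree.Element("SurfaceRecord")
    etree.SubElement(root, "FeatureType").text = "SUR"
    axes = etree.SubElement(root, "Axes")
    for name, inc, size in (("CX", hm.dx, hm.ncols), ("CY", hm.dy, hm.nrows)):
        ax = etree.SubElement(axes, name)
        etree.SubElement(ax, "Increment").text = f"{inc!r}"
        etree.SubElement(ax, "Size").text = str(size)
    etree.SubElement(root, "Unit").text = "um"
    etree.SubElement(root, "Stage").text = hm.stage
    z = np.where(hm.mask, hm.heights, np.nan)
    data = " ".join("NaN" if not np.isfinite(v) else f"{v:.17g}"
                    for v in z.ravel())
    etree.SubElement(root, "DataList").text = data
    xml = etree.tostring(root, pretty_print=True, xml_declaration=True,
                         encoding="UTF-8")
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("main.xml", xml)


def _read_x3p_like(path: Path) -> HeightMap:
    try:
        with zipfile.ZipFile(path) as zf:
            with zf.open("main.xml") as fh:
                tree = etree.parse(io.BytesIO(fh.read()))
    except (zipfile.BadZipFile, KeyError) as exc:
        raise HeightMapError(f"{path}: not a valid x3p-like container") from exc
    root = tree.getroot()

    def _text(xpath):
        el = root.find(xpath)
        if el is None or el.text is None:
            raise HeightMapError(f"{path}: missing element {xpath}")
        return el.text

    dx = float(_text("Axes/CX/Increment"))
    dy = float(_text("Axes/CY/Increment"))
    ncols = int(_text("Axes/CX/Size"))
    nrows = int(_text("Axes/CY/Size"))
    stage_el = root.find("Stage")
    stage = stage_el.text if stage_el is not None and stage_el.text else "raw"
    tokens = _text("DataList").split()
    if len(tokens) != nrows * ncols:
        raise HeightMapError(
            f"{path}: data list length {len(tokens)} != {nrows}x{ncols}")
    heights = np.array([float("nan") if t.lower() == "nan" else float(t)
                        for t in tokens]).reshape(nrows, ncols)
    mask = np.isfinite(heights)
    if not mask.any():
        raise HeightMapError(f"{path}: all points are non-measured")
    return HeightMap(heights, dx=dx, dy=dy, mask=mask, stage=stage)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_height_map(path, format: str = None) -> HeightMap:
    """Read a height map from ``csv-grid`` or ``x3p-like`` format.

    If *format* is None it is inferred from the suffix (``.x3p``/``.zip``
    -> x3p-like, else csv-grid).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "x3p-like" if path.suffix.lower() in {".x3p", ".zip"} else "csv-grid"
    if format == "csv-grid":
        return _read_csv_grid(path)
    if format == "x3p-like":
        return _read_x3p_like(path)
    raise HeightMapError(f"unknown format {format!r}")


def write_height_map(hm: HeightMap, path, format: str = None):
    """Write *hm*; round-trips bit-exactly through either format."""
    path = Path(path)
    if format is None:
        format = "x3p-like" if path.suffix.lower() in {".x3p", ".zip"} else "csv-grid"
    if format == "csv-grid":
        _write_csv_grid(hm, path)
    elif format == "x3p-like":
        _write_x3p_like(hm, path)
    else:
        raise HeightMapError(f"unknown format {format!r}")
    return path


def validate_measured_fraction(hm: HeightMap, threshold: float = 0.80):
    """Accept the map iff its measured-point fraction is >= *threshold*.

    The instrument-side quality rule: surfaces with fewer than 80% of
    recorded points are discarded before any filtering.

    Returns
    -------
    (accepted, fraction) : (bool, float)
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if hm.heights.size == 0:
        raise HeightMapError("empty grid")
    frac = hm.measured_fraction
    return frac >= threshold, frac


def fill_nonmeasured(hm: HeightMap, threshold: float = 0.80) -> HeightMap:
    """Fill non-measured points by bilinear interpolation from measured
    neighbours.

    Each masked point gets the average of a 1-D linear interpolation along
    its row and one along its column (nearest measured neighbour on each
    side); at borders where only one side exists the nearest measured value
    is used. Deterministic and order-independent; idempotent on fully
    measured maps. The map must first pass the measured-fraction rule.
    """
    ok, frac = validate_measured_fraction(hm, threshold)
    if not ok:
        raise HeightMapError(
            f"measured fraction {frac:.3f} below threshold {threshold:.2f}")
    if hm.mask.all():
        return hm.copy()

    z = hm.heights
    mask = hm.mask

    def _interp_lines(zz, mm, coords):
        out = np.full_like(zz, np.nan)
        for i in range(zz.shape[0]):
            good = mm[i]
            if good.sum() == 0:
                continue
            out[i] = np.interp(coords, coords[good], zz[i, good])
        return out

    x = hm.x_coords()
    y = hm.y_coords()
    by_row = _interp_lines(z, mask, x)
    by_col = _interp_lines(z.T, mask.T, y).T
    filled = np.where(mask, z, np.nanmean(np.stack([by_row, by_col]), axis=0))
    # isolated rows/columns with no measured point at all: fall back to the
    # nearest measured value on the full grid
    still = ~np.isfinite(filled)
    if still.any():
        from scipy.ndimage import distance_transform_edt
        idx = distance_transform_edt(~mask, return_distances=False,
                                     return_indices=True)
        filled[still] = z[idx[0][still], idx[1][still]]
    return HeightMap(filled, hm.dx, hm.dy,
                     mask=np.ones_like(mask), stage=hm.stage)
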