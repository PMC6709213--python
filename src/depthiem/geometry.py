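"""Stereoscopic stimulus geometry.

The experiment renders a sphere at positions on a staggered triangular grid
spanning the horizontal (x) and depth (z) axes of a 3D scene. The viewer's
two eyes sit at x = ±eye_offset in the fixation plane and fixate a point at
``fixation_distance`` scene units straight ahead (z = 0 is the fixation
plane; positive z is *nearer* to the viewer). This module constructs the
grid and converts scene coordinates to degrees of visual angle and to
relative binocular disparity in arcminutes.

Sign convention: near (crossed) disparities are negative, far (uncrossed)
disparities positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ViewerGeometry",
    "GridSpacing",
    "StimulusLocation",
    "StimulusGrid",
    "disparity_of_point",
    "scene_to_ecc",
    "sphere_radius_at",
    "make_grid",
    "Z_ROWS",
]

#: Canonical z coordinate of each grid row, far to near, scene units.
Z_ROWS: tuple[float, ...] = (-1.5, -0.9, -0.3, 0.3, 0.9, 1.5)

ARCMIN_PER_RAD = 60.0 * 180.0 / math.pi

# Sphere radius in scene units is anchored at the printed extremes:
# viewing distance d = 11.5 (furthest row) -> 0.73, d = 8.5 (nearest) -> 0.55,
# linear in d between the anchors.
_RADIUS_ANCHORS = ((8.5, 0.55), (11.5, 0.73))


class GeometryError(ValueError):
    """Invalid viewing geometry or grid configuration."""


@dataclass(frozen=True)
class ViewerGeometry:
    """Viewing parameters of the stereoscopic display, in scene units.

    ``eye_offset`` is half the interpupillary distance (eyes at x = ±0.4),
    ``fixation_distance`` the screen-to-viewer distance along z.
    """

    eye_offset: float = 0.4
    fixation_distance: float = 10.0
    vertical_fov_deg: float = 25.0
    horizontal_fov_deg: float = 33.0
    screen_px: tuple[int, int] = (800, 600)

    def __post_init__(self) -> None:
        if not self.eye_offset > 0:
            raise GeometryError("eye_offset must be positive")
        if not self.fixation_distance > self.eye_offset:
            raise GeometryError("fixation_distance must exceed eye_offset")
        for fov in (self.vertical_fov_deg, self.horizontal_fov_deg):
            if not 0 < fov < 180:
                raise GeometryError("fields of view must lie in (0, 180) degrees")


DEFAULT_GEOMETRY = ViewerGeometry()


def disparity_of_point(x, z, geom: ViewerGeometry = DEFAULT_GEOMETRY):
    """Relative binocular disparity of a scene point, in arcminutes.

    Disparity is the vergence demand of the point minus the vergence demand
    of fixation:

        2*atan(e/D) - [atan((x+e)/(D-z)) - atan((x-e)/(D-z))]

    with e = eye_offset and D = fixation_distance. On-axis near points
    (z > 0) yield negative (crossed) disparity. Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    e = geom.eye_offset
    d = geom.fixation_distance - z
    if np.any(d <= 0):
        raise GeometryError("point at or behind the eyes (fixation_distance - z <= 0)")
    fix_vergence = 2.0 * math.atan(e / geom.fixation_distance)
    point_vergence = np.arctan((x + e) / d) - np.arctan((x - e) / d)
    out = (fix_vergence - point_vergence) * ARCMIN_PER_RAD
    return float(out) if out.ndim == 0 else out


def scene_to_ecc(x, z, geom: ViewerGeometry = DEFAULT_GEOMETRY):
    """Eccentricity of a scene point in degrees of visual angle.

    Measured from the cyclopean point to the target's depth plane:
    atan(|x| / (D - z)). Symmetric in ±x.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    d = geom.fixation_distance - z
    if np.any(d <= 0):
        raise GeometryError("point at or behind the eyes (fixation_distance - z <= 0)")
    out = np.degrees(np.arctan(np.abs(x) / d))
    return float(out) if out.ndim == 0 else out


def sphere_radius_at(z, geom: ViewerGeometry = DEFAULT_GEOMETRY):
    """Rendered sphere radius (scene units) at depth z.

    The apparent angular size is held constant across depth by scaling the
    rendered radius linearly in viewing distance d = D - z, anchored at
    d = 11.5 -> 0.73 and d = 8.5 -> 0.55 scene units. Extrapolation beyond
    the anchors is permitted with a warning.
    """
    z = np.asarray(z, dtype=float)
    d = geom.fixation_distance - z
    (d0, r0), (d1, r1) = _RADIUS_ANCHORS
    if np.any(d < d0) or np.any(d > d1):
        warnings.warn("sphere radius extrapolated beyond the grid's depth range",
                      stacklevel=2)
    out = r0 + (r1 - r0) * (d - d0) / (d1 - d0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GridSpacing:
    """Layout of the staggered stimulus grid.

    Columns are 2*n_cols evenly spaced angular positions spanning
    ±ecc_max_deg; alternate z-rows take alternate column subsets, so rows
    are staggered by half the column spacing and a grid plus its mirror
    tiles all 12 columns. The innermost column then falls at
    ecc_max_deg/(2*n_cols - 1) (0.89 deg under defaults).
    """

    z_rows: tuple[float, ...] = Z_ROWS
    n_cols: int = 6
    ecc_max_deg: float = 9.8

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.ecc_max_deg <= 0:
            raise GeometryError("invalid grid spacing")
        if len(set(self.z_rows)) != len(self.z_rows):
            raise GeometryError("z rows must be distinct")

    def column_angles(self, row_index: int) -> np.ndarray:
        """Angular x positions (deg) of the columns in a given row."""
        k = np.arange(2 * self.n_cols)
        angles = -self.ecc_max_deg + k * (2 * self.ecc_max_deg) / (2 * self.n_cols - 1)
        return angles[row_index % 2 :: 2]


@dataclass(frozen=True)
class StimulusLocation:
    """One grid position with its derived viewing quantities."""

    row_index: int
    col_index: int
    x_scene: float
    z_scene: float
    ecc_deg: float
    disparity_arcmin: float
    sphere_radius_scene: float


@dataclass(frozen=True)
class StimulusGrid:
    """The 36 stimulus locations of one run (optionally mirrored in x)."""

    locations: tuple[StimulusLocation, ...]
    mirrored: bool
    spacing: GridSpacing = field(default=GridSpacing())
    geom: ViewerGeometry = field(default=DEFAULT_GEOMETRY)

    def __len__(self) -> int:
        return len(self.locations)

    @property
    def n_rows(self) -> int:
        return len(self.spacing.z_rows)

    @property
    def n_cols(self) -> int:
        return self.spacing.n_cols

    def location(self, row_index: int, col_index: int) -> StimulusLocation:
        for loc in self.locations:
            if loc.row_index == row_index and loc.col_index == col_index:
                return loc
        raise KeyError(f"no grid location at row {row_index}, col {col_index}")

    def xz_pairs(self) -> set[tuple[float, float]]:
        return {(round(loc.x_scene, 9), round(loc.z_scene, 9)) for loc in self.locations}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row_index": [l.row_index for l in self.locations],
                "col_index": [l.col_index for l in self.locations],
                "x_scene": [l.x_scene for l in self.locations],
                "z_scene": [l.z_scene for l in self.locations],
                "ecc_deg": [l.ecc_deg for l in self.locations],
                "disparity_arcmin": [l.disparity_arcmin for l in self.locations],
                "sphere_radius_scene": [l.sphere_radius_scene for l in self.locations],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path, mirrored: bool = False) -> "StimulusGrid":
        df = pd.read_csv(path)
        locs = tuple(
            StimulusLocation(
                int(r.row_index), int(r.col_index), float(r.x_scene),
                float(r.z_scene), float(r.ecc_deg), float(r.disparity_arcmin),
                float(r.sphere_radius_scene),
            )
            for r in df.itertuples()
        )
        return StimulusGrid(locations=locs, mirrored=mirrored)

    def row_mean_disparity(self) -> np.ndarray:
        """Mean disparity (arcmin) of each z row of this grid."""
        out = np.zeros(self.n_rows)
        for i in range(self.n_rows):
            vals = [l.disparity_arcmin for l in self.locations if l.row_index == i]
            out[i] = float(np.mean(vals))
        return out


def make_grid(
    geom: ViewerGeometry = DEFAULT_GEOMETRY,
    spacing: GridSpacing = GridSpacing(),
    mirrored: bool = False,
) -> StimulusGrid:
    """Construct the staggered stimulus grid.

    Each of the six z rows receives ``n_cols`` locations (half left, half
    right of fixation). ``mirrored=True`` negates every x coordinate, which
    under the staggered layout yields the complementary column set: the
    union of a grid and its mirror covers 2*n_cols distinct x columns per
    row. Deterministic.
    """
    if spacing.ecc_max_deg > geom.horizontal_fov_deg / 2:
        raise GeometryError(
            f"grid eccentricity {spacing.ecc_max_deg} deg exceeds the displayable "
            f"half-field {geom.horizontal_fov_deg / 2} deg"
        )
    locations: list[StimulusLocation] = []
    for i, z in enumerate(spacing.z_rows):
        d = geom.fixation_distance - z
        angles = spacing.column_angles(i)
        xs = d * np.tan(np.radians(angles))
        if mirrored:
            xs = np.sort(-xs)
        radius = sphere_radius_at(z, geom)
        for j, x in enumerate(xs):
            locations.append(
                StimulusLocation(
                    row_index=i,
                    col_index=j,
                    x_scene=float(x),
                    z_scene=float(z),
                    ecc_deg=scene_to_ecc(x, z, geom),
                    disparity_arcmin=disparity_of_point(x, z, geom),
                    sphere_radius_scene=float(radius),
                )
            )
    return StimulusGrid(locations=tuple(locations), mirrored=mirrored,
                        spacing=spacing, geom=geom)
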