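"""Whole-panicle digital traits: PCA frame, voxel count, projected-area sweep.

The panicle's intrinsic coordinate system is obtained by principal component
analysis of the point coordinates: the first principal direction is the
Z-axis (the rachis direction, sign fixed by an up-hint), the second and third
are X and Y.  The origin is the lowest cloud point along Z.

Projected panicle area (PPA) is measured by a rotational sweep: a projection
plane containing the Z-axis is rotated about it in 5-degree steps over
[0, 180), giving 36 silhouette areas whose maximum, minimum, and mean are the
whole-panicle area traits.  The mean (averaged projected area) is the PPA used
downstream to normalize panicle gas exchange.  Silhouette area is the area of
the region enclosed by the boundary of the projected 2D points, by default an
alpha shape (concave boundary; truer for branched silhouettes), with convex
hull and occupancy-raster alternatives.

Voxel count (VC, a volume proxy) bins points on a regular 3D grid and counts
occupied cells.  Color proportions G/(R+G) and R/(R+G) summarize greenness,
either summing channel intensities (default) or counting green-dominant
points (``mode='classify'``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .cloud import ColoredPointCloud

__all__ = [
    "PanicleFrame",
    "VoxelGrid",
    "ProjectionSweep",
    "TraitRecord",
    "fit_panicle_frame",
    "voxelize",
    "projected_area",
    "projection_sweep",
    "color_proportions",
    "extract_traits",
    "alpha_shape_area",
    "PanicleTraitExtractor",
    "GeometryError",
]

BOUNDARY_METHODS = ("alpha_shape", "convex_hull", "raster")


class GeometryError(ValueError):
    """Raised on degenerate geometry (collinear or coincident points)."""


@dataclass
class PanicleFrame:
    """PCA-derived orthonormal frame: Z = first principal direction."""

    origin: np.ndarray
    z_axis: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray

    def to_local(self, coords: np.ndarray) -> np.ndarray:
        """Express world coordinates in the frame (columns: x, y, z)."""
        rel = np.asarray(coords) - self.origin
        basis = np.column_stack([self.x_axis, self.y_axis, self.z_axis])
        return rel @ basis


@dataclass
class VoxelGrid:
    """Occupied cells of a regular 3D grid; voxel_count is the VC trait."""

    voxel_size: float
    occupied: set
    min_corner: np.ndarray

    @property
    def voxel_count(self) -> int:
        return len(self.occupied)


@dataclass
class ProjectionSweep:
    """Rotational projected-area sweep plus axis-perpendicular projections."""

    angles: np.ndarray
    areas: np.ndarray
    area_perp_x: float
    area_perp_y: float

    @property
    def area_max(self) -> float:
        return float(self.areas.max())

    @property
    def area_min(self) -> float:
        return float(self.areas.min())

    @property
    def area_mean(self) -> float:
        return float(self.areas.mean())


@dataclass
class TraitRecord:
    """Whole-panicle digital traits.

    ``ppa`` is the averaged projected area over the sweep — the normalizer for
    panicle gas-exchange fluxes.  ``green_prop`` + ``red_prop`` = 1 whenever
    the red+green total is positive.
    """

    ppa: float
    area_max: float
    area_min: float
    area_perp_x: float
    area_perp_y: float
    voxel_count: int
    green_prop: float
    red_prop: float

    def as_dict(self) -> dict:
        return {
            "ppa": self.ppa,
            "area_max": self.area_max,
            "area_min": self.area_min,
            "area_perp_x": self.area_perp_x,
            "area_perp_y": self.area_perp_y,
            "voxel_count": self.voxel_count,
            "green_prop": self.green_prop,
            "red_prop": self.red_prop,
        }


def fit_panicle_frame(
    cloud: ColoredPointCloud, up_hint: np.ndarray | None = None
) -> PanicleFrame:
    """Fit the PCA frame: Z = first principal direction, origin = lowest point.

    The eigenvector signs are ambiguous; Z is oriented so that its dot product
    with ``up_hint`` (default world +Z, the capture-rig vertical) is
    non-negative, and the X/Y pair is completed to a right-handed basis.

    Raises
    ------
    GeometryError
        For fewer than 3 points or a degenerate (collinear/coincident)
        coordinate covariance.
    """
    coords = cloud.coords
    if coords.shape[0] < 3:
        raise GeometryError("frame fitting needs at least 3 points")
    if up_hint is None:
        up_hint = np.array([0.0, 0.0, 1.0])
    up_hint = np.asarray(up_hint, dtype=np.float64)

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / (coords.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = np.trace(cov)
    if scale <= 0 or evals[1] / max(evals[0], 1e-300) < 1e-12:
        raise GeometryError("degenerate coordinate covariance (collinear or coincident points)")

    z = evecs[:, 0]
    if np.dot(z, up_hint) < 0:
        z = -z
    x = evecs[:, 1]
    # eigenvector signs are arbitrary; orient X by the data's own asymmetry
    # (third moment of the projections) so the frame is fully intrinsic and
    # transforms covariantly under rigid motion of the cloud
    tx = centered @ x
    if np.sum(tx**3) < 0:
        x = -x
    y = np.cross(z, x)  # right-handed completion
    y /= np.linalg.norm(y)
    t = coords @ z
    origin = coords[np.argmin(t)]
    return PanicleFrame(origin=origin, z_axis=z, x_axis=x, y_axis=y)


def voxelize(cloud: ColoredPointCloud, voxel_size: float) -> VoxelGrid:
    """Bin points on a regular grid anchored at the cloud's minimum corner."""
    if voxel_size <= 0:
        raise ValueError(f"voxel_size must be positive, got {voxel_size}")
    min_corner = cloud.coords.min(axis=0)
    idx = np.floor((cloud.coords - min_corner) / voxel_size).astype(np.int64)
    occupied = set(map(tuple, idx))
    return VoxelGrid(voxel_size=voxel_size, occupied=occupied, min_corner=min_corner)


def _projected_2d(
    cloud: ColoredPointCloud, frame: PanicleFrame, angle_deg: float
) -> np.ndarray:
    """Project onto the plane containing z_axis whose normal is y_axis rotated
    by ``angle_deg`` about z_axis; returns in-plane (u, z) coordinates."""
    theta = np.deg2rad(angle_deg)
    # in-plane horizontal axis: x_axis rotated by angle about z
    u = np.cos(theta) * frame.x_axis + np.sin(theta) * frame.y_axis
    rel = cloud.coords - frame.origin
    return np.column_stack([rel @ u, rel @ frame.z_axis])


def alpha_shape_area(points2d: np.ndarray, alpha: float | None = None) -> float:
    """Area of the alpha shape of 2D points.

    Classical Delaunay construction: triangulate, keep triangles whose
    circumradius is at most ``alpha``, and sum their areas.  For dense
    samplings with alpha a few times the point spacing this measures the area
    of the (possibly concave) region the points fill.

    When ``alpha`` is None it defaults to 3× the median Delaunay edge length
    of the points.  That scale tracks the typical triangle size directly, so
    it stays meaningful when the projection stacks near-coincident points
    (front and back of a silhouette), which deflate nearest-neighbor spacing
    statistics.
    """
    if len(points2d) < 3:
        return 0.0
    try:
        tri = Delaunay(points2d)
    except QhullError:
        return 0.0
    p = points2d[tri.simplices]
    a, b, c = p[:, 0], p[:, 1], p[:, 2]
    ab, ac, bc = b - a, c - a, c - b
    la = np.linalg.norm(bc, axis=1)
    lb = np.linalg.norm(ac, axis=1)
    lc = np.linalg.norm(ab, axis=1)
    cross = np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    area2 = cross  # twice the triangle area
    if alpha is None:
        alpha = 3.0 * float(np.median(np.concatenate([la, lb, lc])))
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(area2 > 0, la * lb * lc / (2 * area2), np.inf)
    keep = circumradius <= alpha
    return float(np.sum(area2[keep]) / 2.0)


def _raster_area(points2d: np.ndarray, cell: float) -> float:
    """Occupancy-grid silhouette area: occupied cells × cell area."""
    idx = np.floor((points2d - points2d.min(axis=0)) / cell).astype(np.int64)
    n_occ = len(np.unique(idx, axis=0))
    return float(n_occ) * cell * cell


def _median_nn_spacing(points2d: np.ndarray) -> float:
    sample = points2d if len(points2d) <= 20000 else points2d[:: len(points2d) // 20000 + 1]
    tree = cKDTree(points2d)
    dist, _ = tree.query(sample, k=2)
    return float(np.median(dist[:, 1]))


def projected_area(
    cloud: ColoredPointCloud,
    frame: PanicleFrame,
    angle_deg: float,
    boundary_method: str = "alpha_shape",
    alpha: float | None = None,
) -> float:
    """Silhouette area of the cloud projected at one sweep angle.

    The projection plane contains the frame's Z-axis; its normal is the
    Y-axis rotated by ``angle_deg`` about Z (so angle 0 projects along Y).
    The area is the region enclosed by the boundary of the projected 2D
    points, measured by the chosen boundary method.  When the cloud carries a
    metric scale (``units_per_cm``), the area is returned in cm².

    Fewer than 3 projected points yield area 0 with a warning.
    """
    if boundary_method not in BOUNDARY_METHODS:
        raise ValueError(
            f"boundary_method must be one of {BOUNDARY_METHODS}, got {boundary_method!r}"
        )
    pts = _projected_2d(cloud, frame, angle_deg)
    if len(pts) < 3:
        warnings.warn("fewer than 3 projected points; area is 0", stacklevel=2)
        return 0.0
    if boundary_method == "convex_hull":
        try:
            area = float(ConvexHull(pts).volume)  # 2D: volume is the area
        except QhullError:
            warnings.warn("degenerate projection; area is 0", stacklevel=2)
            area = 0.0
    elif boundary_method == "alpha_shape":
        area = alpha_shape_area(pts, alpha)
    else:  # raster
        if alpha is not None:
            cell = alpha
        else:
            cell = 3.0 * _median_nn_spacing(pts)
            if cell == 0:
                cell = 1e-9
        area = _raster_area(pts, cell)
    if cloud.units_per_cm is not None:
        area /= cloud.units_per_cm**2
    return area


def projection_sweep(
    cloud: ColoredPointCloud,
    frame: PanicleFrame,
    step_deg: float = 5.0,
    boundary_method: str = "alpha_shape",
) -> ProjectionSweep:
    """Rotational projected-area sweep over [0, 180) degrees.

    With the default 5-degree step the sweep emits exactly 36 areas.
    Orthogonal projection is invariant under a 180-degree plane rotation, so
    half a turn covers every distinct silhouette.  Also computes the two
    axis-perpendicular projections (plane normal = X-axis and Y-axis).

    Raises
    ------
    ValueError
        If ``step_deg`` does not divide 180.
    """
    n = 180.0 / step_deg
    if abs(n - round(n)) > 1e-9 or step_deg <= 0:
        raise ValueError(f"step_deg must positively divide 180, got {step_deg}")
    n = int(round(n))
    angles = np.arange(n) * step_deg
    areas = np.array(
        [projected_area(cloud, frame, a, boundary_method) for a in angles]
    )
    # plane normal = x_axis corresponds to sweep angle 90; normal = y_axis to 0
    area_perp_x = projected_area(cloud, frame, 90.0, boundary_method)
    area_perp_y = projected_area(cloud, frame, 0.0, boundary_method)
    return ProjectionSweep(
        angles=angles, areas=areas, area_perp_x=area_perp_x, area_perp_y=area_perp_y
    )


def color_proportions(
    cloud: ColoredPointCloud, mode: str = "intensity"
) -> tuple[float, float]:
    """Green and red proportions of the cloud's coloring.

    ``mode='intensity'`` (default) returns ΣG/(ΣR+ΣG) and ΣR/(ΣR+ΣG) over the
    summed channel intensities; ``mode='classify'`` counts points classified
    green (G > R) versus red among points where the two channels differ or
    are nonzero.

    Raises
    ------
    ValueError
        If the red+green total is zero (all-blue/black cloud).
    """
    r = cloud.colors[:, 0]
    g = cloud.colors[:, 1]
    if mode == "intensity":
        tot = r.sum() + g.sum()
        if tot == 0:
            raise ValueError("undefined color proportions: ΣR + ΣG = 0")
        green = float(g.sum() / tot)
    elif mode == "classify":
        n = cloud.point_count
        if n == 0 or (r.sum() + g.sum()) == 0:
            raise ValueError("undefined color proportions: no red/green signal")
        green = float(np.mean(g > r))
    else:
        raise ValueError(f"mode must be 'intensity' or 'classify', got {mode!r}")
    return green, 1.0 - green


def extract_traits(
    cloud: ColoredPointCloud,
    frame: PanicleFrame | None = None,
    voxel_size: float | None = None,
    step_deg: float = 5.0,
    boundary_method: str = "alpha_shape",
    color_mode: str = "intensity",
    up_hint: np.ndarray | None = None,
) -> TraitRecord:
    """Bundle the whole-panicle digital traits into a :class:`TraitRecord`.

    PPA is the sweep's averaged projected area; voxel count uses 2× the
    median nearest-neighbor spacing when no grid resolution is given.
    """
    from .segmentation import default_voxel_size

    if frame is None:
        frame = fit_panicle_frame(cloud, up_hint)
    if voxel_size is None:
        voxel_size = default_voxel_size(cloud)
    sweep = projection_sweep(cloud, frame, step_deg, boundary_method)
    # voxelize in frame-local coordinates so the voxel count is a property of
    # the panicle, not of its pose on the capture rig
    local = ColoredPointCloud(
        frame.to_local(cloud.coords), cloud.colors, units_per_cm=cloud.units_per_cm
    )
    grid = voxelize(local, voxel_size)
    green, red = color_proportions(cloud, mode=color_mode)
    return TraitRecord(
        ppa=sweep.area_mean,
        area_max=sweep.area_max,
        area_min=sweep.area_min,
        area_perp_x=sweep.area_perp_x,
        area_perp_y=sweep.area_perp_y,
        voxel_count=grid.voxel_count,
        green_prop=green,
        red_prop=red,
    )


class PanicleTraitExtractor(TransformerMixin, BaseEstimator):
    """Transform segmented panicle clouds into a digital-trait feature matrix.

    scikit-learn transformer over a collection of clouds: ``transform`` takes
    a list of :class:`ColoredPointCloud` (or (N, 6) xyzrgb arrays) and returns
    a pandas DataFrame with one row per panicle and columns
    ``ppa, area_max, area_min, area_perp_x, area_perp_y, voxel_count,
    green_prop, red_prop``.

    Parameters mirror :func:`extract_traits`; ``fit`` is stateless and kept
    for pipeline compatibility.
    """

    def __init__(
        self,
        step_deg: float = 5.0,
        boundary_method: str = "alpha_shape",
        voxel_size: float | None = None,
        color_mode: str = "intensity",
        up_hint: tuple | None = None,
    ):
        self.step_deg = step_deg
        self.boundary_method = boundary_method
        self.voxel_size = voxel_size
        self.color_mode = color_mode
        self.up_hint = up_hint

    def fit(self, X, y=None) -> "PanicleTraitExtractor":
        self.n_features_out_ = 8
        return self

    def transform(self, X):
        import pandas as pd

        rows = []
        for item in X:
            cloud = (
                item
                if isinstance(item, ColoredPointCloud)
                else ColoredPointCloud.from_array(np.asarray(item))
            )
            rec = extract_traits(
                cloud,
                voxel_size=self.voxel_size,
                step_deg=self.step_deg,
                boundary_method=self.boundary_method,
                color_mode=self.color_mode,
                up_hint=None if self.up_hint is None else np.asarray(self.up_hint),
            )
            rows.append(rec.as_dict())
        return pd.DataFrame(rows)
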