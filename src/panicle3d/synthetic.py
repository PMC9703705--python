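"""Synthetic data with known ground truth for every pipeline stage.

Real reconstructed panicle clouds are not redistributable, so the test
surface is built from generators that emulate their structure: a branched
panicle cloud (curved rachis, primary branches bearing Gaussian spikelet
blobs) with an axial green→red color gradient standing in for the
chlorophyll gradient of a ripening panicle, optional gray background-clutter
clusters, analytic primitives (sphere shell, cylinder, box) whose silhouette
areas are known in closed form, and factorial gas-exchange cohorts with
programmed treatment effects.

Every generator is a pure function of its parameters and seed.

The color model is chosen so VARI separates classes cleanly: green-dominant
points sample RGB ≈ (N(60,15), N(180,20), N(50,15)), red-dominant points
swap the R and G channels, and clutter is gray N(120,10) on all channels
(VARI ≈ 0).  A green-dominant point therefore has an expected intensity
ratio G/(R+G) of 180/240 = 0.75 and a red-dominant point 0.25, so a cloud
whose green-dominant fraction is f has expected intensity green proportion
0.25 + 0.5·f, while the point-classification mode (green if G > R) estimates
f directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cloud import ColoredPointCloud

__all__ = [
    "SyntheticPanicleSpec",
    "GroundTruth",
    "generate_panicle",
    "generate_primitive",
    "generate_gas_exchange_cohort",
    "generate_correlated_traits",
    "GREEN_MEAN_RGB",
    "RED_MEAN_RGB",
]

GREEN_MEAN_RGB = (60.0, 180.0, 50.0)
RED_MEAN_RGB = (180.0, 60.0, 50.0)
_COLOR_SD = (15.0, 20.0, 15.0)
_GRAY_MEAN, _GRAY_SD = 120.0, 10.0


@dataclass
class SyntheticPanicleSpec:
    """Parameters of the branched synthetic panicle.

    Defaults approximate a primary rice panicle at grain filling: a ~15 cm
    rachis with a gentle arc, ~10 primary branches each bearing ~8 spikelet
    blobs, reconstruction density of ~150 points per spikelet.  The green
    gradient runs from the top (youngest spikelets, green) to the bottom;
    clutter entries are (offset, size, color) background clusters.
    """

    rachis_length: float = 15.0
    n_primary_branches: int = 10
    spikelets_per_branch: int = 8
    points_per_spikelet: int = 150
    green_gradient: tuple[float, float] = (0.9, 0.4)
    noise_sd: float = 0.05
    bend: float = 2.0
    branch_length: float = 4.0
    spikelet_sd: float = 0.25
    clutter: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_primary_branches, self.spikelets_per_branch, self.points_per_spikelet
        ) < 1:
            raise ValueError("all counts must be >= 1")
        lo, hi = min(self.green_gradient), max(self.green_gradient)
        if lo < 0 or hi > 1:
            raise ValueError("green_gradient fractions must lie in [0, 1]")
        if self.rachis_length <= 0 or self.noise_sd < 0:
            raise ValueError("rachis_length must be positive and noise_sd non-negative")


@dataclass
class GroundTruth:
    """Per-point generation labels aligned with the generated cloud."""

    is_panicle: np.ndarray
    is_green: np.ndarray  # green-dominant label; False = red-dominant (panicle only)
    green_gradient: tuple[float, float]

    def slice_green_fraction(self, z: np.ndarray, n_slices: int = 10) -> np.ndarray:
        """True green-dominant fraction per equal-Z slice (slice 1 top-most)."""
        zp = z[self.is_panicle]
        g = self.is_green[self.is_panicle]
        z_min, z_max = zp.min(), zp.max()
        width = (z_max - z_min) / n_slices
        j = np.clip(np.floor((zp - z_min) / width).astype(int), 0, n_slices - 1)
        k = (n_slices - 1) - j
        out = np.full(n_slices, np.nan)
        for s in range(n_slices):
            m = k == s
            if m.any():
                out[s] = g[m].mean()
        return out


def _sample_colors(rng: np.random.Generator, is_green: np.ndarray) -> np.ndarray:
    n = len(is_green)
    means = np.where(
        is_green[:, None], np.asarray(GREEN_MEAN_RGB), np.asarray(RED_MEAN_RGB)
    )
    colors = rng.normal(means, np.asarray(_COLOR_SD), size=(n, 3))
    return np.clip(colors, 0, 255)


def generate_panicle(
    spec: SyntheticPanicleSpec | None = None, **kwargs
) -> tuple[ColoredPointCloud, GroundTruth]:
    """Generate a branched panicle-like cloud with known per-point labels.

    The rachis is a quadratic arc (so the PCA axis and the chord differ
    slightly), branches radiate at regular azimuths with a downward droop,
    and each spikelet is an isotropic Gaussian blob.  A point is
    green-dominant with probability interpolated linearly along height
    between the gradient's bottom and top fractions.  Clutter clusters from
    ``spec.clutter`` — (offset, size, color) with color one of
    ``'gray'``/``'green'``/``'red'`` or an RGB triple — are appended after
    the panicle points.
    """
    if spec is None:
        spec = SyntheticPanicleSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a spec or keyword fields, not both")
    rng = np.random.default_rng(spec.seed)
    L = spec.rachis_length

    coords_list, height_list = [], []
    # rachis curve points: stratified along the arc so the axis is contiguous
    n_rachis = max(200, spec.n_primary_branches * 40)
    s = (np.arange(n_rachis) + rng.uniform(size=n_rachis)) / n_rachis
    rachis = np.column_stack([spec.bend * s**2, np.zeros(n_rachis), s * L])
    coords_list.append(rachis + rng.normal(0, spec.noise_sd, rachis.shape))
    height_list.append(s)

    attach = np.linspace(0.08, 0.95, spec.n_primary_branches)
    azimuth = np.arange(spec.n_primary_branches) * 2.399963  # golden angle
    for a, phi in zip(attach, azimuth):
        base = np.array([spec.bend * a**2, 0.0, a * L])
        # branch direction: outward with a droop toward the tip
        direction = np.array(
            [np.cos(phi) * 0.8, np.sin(phi) * 0.8, -0.35]
        )
        direction /= np.linalg.norm(direction)
        # points along the branch axis keep the component connected,
        # as reconstructed branches are in real clouds
        n_axis = max(40, int(spec.branch_length / 0.05))
        f_axis = (np.arange(n_axis) + rng.uniform(size=n_axis)) / n_axis
        axis_pts = base + np.outer(f_axis * spec.branch_length, direction)
        axis_pts = axis_pts + rng.normal(0, spec.noise_sd, axis_pts.shape)
        coords_list.append(axis_pts)
        height_list.append(np.clip(axis_pts[:, 2] / L, 0, 1))
        frac = np.linspace(0.15, 1.0, spec.spikelets_per_branch)
        for f in frac:
            center = base + direction * (f * spec.branch_length)
            pts = center + rng.normal(
                0, spec.spikelet_sd, (spec.points_per_spikelet, 3)
            )
            pts += rng.normal(0, spec.noise_sd, pts.shape)
            coords_list.append(pts)
            height_list.append(np.full(len(pts), np.clip(center[2] / L, 0, 1)))

    # apical spikelets at the rachis tip (panicles terminate in a spikelet)
    tip = np.array([spec.bend, 0.0, L])
    for dz in (0.0, -0.4 * spec.spikelet_sd * 3):
        pts = tip + [0, 0, dz] + rng.normal(
            0, spec.spikelet_sd, (spec.points_per_spikelet, 3)
        )
        coords_list.append(pts)
        height_list.append(np.clip(pts[:, 2] / L, 0, 1))

    coords = np.vstack(coords_list)
    height = np.concatenate(height_list)
    top_frac, bottom_frac = spec.green_gradient
    p_green = bottom_frac + (top_frac - bottom_frac) * height
    is_green = rng.uniform(size=len(coords)) < p_green
    colors = _sample_colors(rng, is_green)
    is_panicle = np.ones(len(coords), dtype=bool)

    for offset, size, color in spec.clutter:
        pts = np.asarray(offset, dtype=float) + rng.normal(0, 1.0, (int(size), 3))
        if isinstance(color, str):
            if color == "gray":
                cl = np.clip(
                    rng.normal(_GRAY_MEAN, _GRAY_SD, (int(size), 3)), 0, 255
                )
            elif color == "green":
                cl = _sample_colors(rng, np.ones(int(size), dtype=bool))
            elif color == "red":
                cl = _sample_colors(rng, np.zeros(int(size), dtype=bool))
            else:
                raise ValueError(f"unknown clutter color {color!r}")
        else:
            cl = np.tile(np.asarray(color, dtype=float), (int(size), 1))
        coords = np.vstack([coords, pts])
        colors = np.vstack([colors, cl])
        is_panicle = np.concatenate([is_panicle, np.zeros(int(size), dtype=bool)])
        is_green = np.concatenate([is_green, np.zeros(int(size), dtype=bool)])

    cloud = ColoredPointCloud(coords, colors)
    truth = GroundTruth(
        is_panicle=is_panicle, is_green=is_green, green_gradient=spec.green_gradient
    )
    return cloud, truth


def generate_primitive(
    shape: str, params: dict | None = None, n_points: int = 10000, seed: int = 0
) -> ColoredPointCloud:
    """Sample an analytic primitive with uniform green color.

    Shapes and parameters:

    - ``sphere_shell``: uniform on a sphere surface; ``radius`` (default 1).
      Every silhouette is the disc of area π·r².
    - ``cylinder``: uniform in a solid cylinder along Z; ``radius`` (0.5) and
      ``height`` (10).  Any silhouette through the axis is the 2r×h rectangle.
    - ``box``: uniform in an axis-aligned solid box; ``extent`` triple
      (1, 1, 1); the angle-0 silhouette is a known face.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for usable primitives")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if shape == "sphere_shell":
        r = params.get("radius", 1.0)
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        coords = r * v
    elif shape == "cylinder":
        r = params.get("radius", 0.5)
        h = params.get("height", 10.0)
        rho = r * np.sqrt(rng.uniform(size=n_points))
        phi = rng.uniform(0, 2 * np.pi, n_points)
        z = rng.uniform(0, h, n_points)
        coords = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    elif shape == "box":
        ex = np.asarray(params.get("extent", (1.0, 1.0, 1.0)), dtype=float)
        coords = rng.uniform(0, 1, (n_points, 3)) * ex
    else:
        raise ValueError(f"unknown primitive shape {shape!r}")
    colors = np.tile(np.asarray(GREEN_MEAN_RGB), (n_points, 1))
    return ColoredPointCloud(coords, colors)


DEFAULT_BASELINES = {
    # per-area control means in leaf-chamber units:
    # A in µmol CO2 m-2 s-1, E in mol H2O m-2 s-1
    "leaf": {"A": 20.0, "E": 4.0e-3},
    "panicle": {"A": 3.0, "E": 1.0e-3},
}


def generate_gas_exchange_cohort(
    design: dict | None = None,
    effect_sizes: dict | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a factorial gas-exchange cohort with programmed effects.

    ``design`` gives the factor levels and replication, defaulting to the
    2 genotype × 2 treatment × 2 timepoint layout with n = 4 plants per cell:
    ``{"genotypes": [...], "treatments": [...], "timepoints": [...],
    "n_replicates": int, "baselines": {tissue: {"A": mean, "E": mean}}}``.

    ``effect_sizes`` maps ``(tissue, genotype, treatment, timepoint)`` keys
    (any element may be ``None`` as a wildcard) to multiplicative factors
    ``{"A": fA, "E": fE}`` applied to the cell mean.  Noise is Gaussian with
    relative standard deviation ``noise_sd``.  Returns raw whole-organ fluxes
    (``A_raw``, ``E_raw``) with an ``area_cm2`` column, ready for
    :class:`~panicle3d.physiology.GasExchangeNormalizer`.
    """
    design = dict(design or {})
    genotypes = design.get("genotypes", ["TEJ-1", "TEJ-2"])
    treatments = design.get("treatments", ["control", "HS"])
    timepoints = design.get("timepoints", [4, 10])
    n_rep = design.get("n_replicates", 4)
    baselines = design.get("baselines", DEFAULT_BASELINES)
    areas = design.get("areas_cm2", {"leaf": 6.0, "panicle": 40.0})
    effect_sizes = effect_sizes or {}

    def _factor(tissue, geno, treat, tp) -> dict:
        out = {"A": 1.0, "E": 1.0}
        for key, f in effect_sizes.items():
            kt, kg, kr, kp = key
            if (
                (kt is None or kt == tissue)
                and (kg is None or kg == geno)
                and (kr is None or kr == treat)
                and (kp is None or kp == tp)
            ):
                out["A"] *= f.get("A", 1.0)
                out["E"] *= f.get("E", 1.0)
        return out

    rng = np.random.default_rng(seed)
    rows = []
    for tissue in baselines:
        for geno in genotypes:
            for treat in treatments:
                for tp in timepoints:
                    fac = _factor(tissue, geno, treat, tp)
                    mean_a = baselines[tissue]["A"] * fac["A"]
                    mean_e = baselines[tissue]["E"] * fac["E"]
                    area = areas[tissue]
                    for rep in range(n_rep):
                        a = mean_a * (1 + noise_sd * rng.standard_normal())
                        e = mean_e * (1 + noise_sd * rng.standard_normal())
                        rows.append(
                            {
                                "tissue": tissue,
                                "genotype": geno,
                                "treatment": treat,
                                "dap": tp,
                                "replicate": rep + 1,
                                # raw whole-organ fluxes = per-area mean × area
                                "A_raw": a * (area / 1e4),
                                "E_raw": e * (area / 1e4),
                                "area_cm2": area,
                            }
                        )
    return pd.DataFrame(rows)


def generate_correlated_traits(
    n: int, r: float, seed: int = 0, names: tuple[str, str] = ("trait_a", "trait_b")
) -> pd.DataFrame:
    """Bivariate normal replicate table with programmed correlation ``r``."""
    if not -1 <= r <= 1:
        raise ValueError("correlation must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, r], [r, 1.0]])
    x = rng.multivariate_normal([0, 0], cov, size=n)
    return pd.DataFrame(x, columns=list(names))
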