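"""Colored point-cloud container and PLY vertex I/O.

A :class:`ColoredPointCloud` is the geometry carrier used throughout the
package: N points with XYZ coordinates (reconstruction units; an optional
``units_per_cm`` factor supplies metric scale downstream) and RGB intensities
on the canonical 0-255 scale.

The PLY reader handles the vertex element of ASCII and binary-little-endian
files, accepts ``red/green/blue`` as well as ``r/g/b`` color property names,
and rescales float colors stored on 0-1 to 0-255.  Mesh elements (faces) are
ignored; the points are the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ColoredPointCloud", "read_ply", "write_ply", "PLYFormatError"]


class PLYFormatError(ValueError):
    """Raised when a PLY file cannot supply colored vertices."""


_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}

_COLOR_ALIASES = {
    "red": "red", "r": "red",
    "green": "green", "g": "green",
    "blue": "blue", "b": "blue",
}


@dataclass
class ColoredPointCloud:
    """N points with XYZ coordinates and RGB intensities in [0, 255].

    Parameters
    ----------
    coords : (N, 3) float array
        Point coordinates in reconstruction units.
    colors : (N, 3) float array
        R, G, B channel intensities, each in [0, 255].
    units_per_cm : float, optional
        Reconstruction units per centimetre; when set, areas can be reported
        in cm^2 downstream.
    """

    coords: np.ndarray
    colors: np.ndarray
    units_per_cm: float | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.colors = np.asarray(self.colors, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if self.colors.shape != self.coords.shape:
            raise ValueError(
                f"colors shape {self.colors.shape} does not match coords "
                f"shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        if self.colors.size and (self.colors.min() < 0 or self.colors.max() > 255):
            raise ValueError("color intensities must lie in [0, 255]")

    @property
    def point_count(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.point_count

    def subset(self, mask_or_index: np.ndarray) -> "ColoredPointCloud":
        """Return the sub-cloud selected by a boolean mask or index array."""
        idx = np.asarray(mask_or_index)
        return ColoredPointCloud(
            self.coords[idx], self.colors[idx], units_per_cm=self.units_per_cm
        )

    def as_array(self) -> np.ndarray:
        """Stack into a single (N, 6) xyzrgb array (the estimator input form)."""
        return np.hstack([self.coords, self.colors])

    @classmethod
    def from_array(cls, X: np.ndarray, units_per_cm: float | None = None) -> "ColoredPointCloud":
        """Build a cloud from an (N, 6) xyzrgb array."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != 6:
            raise ValueError(f"expected (N, 6) xyzrgb array, got {X.shape}")
        return cls(X[:, :3], X[:, 3:], units_per_cm=units_per_cm)


def _parse_header(fh) -> tuple[str, int, list[tuple[str, str]], int]:
    """Parse the PLY header; return (format, n_vertices, vertex props, data offset)."""
    magic = fh.readline().strip()
    if magic != b"ply":
        raise PLYFormatError("not a PLY file (missing 'ply' magic)")
    fmt = None
    n_vertices = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    while True:
        line = fh.readline()
        if not line:
            raise PLYFormatError("unterminated PLY header")
        tokens = line.decode("ascii", errors="replace").split()
        if not tokens:
            continue
        kw = tokens[0]
        if kw == "comment" or kw == "obj_info":
            continue
        if kw == "format":
            fmt = tokens[1]
        elif kw == "element":
            in_vertex = tokens[1] == "vertex"
            if in_vertex:
                n_vertices = int(tokens[2])
            elif n_vertices is None:
                # a non-vertex element before vertex: unsupported layout
                raise PLYFormatError(
                    f"element '{tokens[1]}' precedes the vertex element; unsupported"
                )
        elif kw == "property" and in_vertex:
            if tokens[1] == "list":
                raise PLYFormatError("list property on vertex element is unsupported")
            props.append((tokens[2].lower(), _PLY_DTYPES[tokens[1]]))
        elif kw == "end_header":
            break
    if fmt not in ("ascii", "binary_little_endian"):
        raise PLYFormatError(f"unsupported PLY format {fmt!r}")
    if n_vertices is None:
        raise PLYFormatError("PLY file has no vertex element")
    return fmt, n_vertices, props, fh.tell()


def read_ply(path: str | Path, units_per_cm: float | None = None) -> ColoredPointCloud:
    """Read a colored point cloud from a PLY file.

    Accepts ASCII and binary-little-endian dialects.  Vertex properties must
    include x, y, z and red/green/blue (or r/g/b); float colors stored on a
    0-1 scale are rescaled to 0-255.

    Raises
    ------
    PLYFormatError
        If the file is not PLY, lacks a coordinate or color property, or
        declares zero vertices.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, n_vertices, props, _ = _parse_header(fh)
        if n_vertices == 0:
            raise PLYFormatError(f"{path}: PLY vertex element is empty")
        names = [p[0] for p in props]
        for need in ("x", "y", "z"):
            if need not in names:
                raise PLYFormatError(f"{path}: missing vertex property '{need}'")
        color_cols: dict[str, str] = {}
        for name in names:
            canon = _COLOR_ALIASES.get(name)
            if canon is not None and canon not in color_cols:
                color_cols[canon] = name
        for need in ("red", "green", "blue"):
            if need not in color_cols:
                raise PLYFormatError(f"{path}: missing vertex color property '{need}'")

        dtype = np.dtype([(n, "<" + d) for n, d in props])
        if fmt == "ascii":
            text = fh.read().decode("ascii")
            rows = text.split()
            ncol = len(props)
            if len(rows) < n_vertices * ncol:
                raise PLYFormatError(f"{path}: truncated ASCII vertex data")
            flat = np.array(rows[: n_vertices * ncol], dtype=np.float64)
            table = flat.reshape(n_vertices, ncol)
            # honor the declared storage type so ASCII and binary agree
            data = {
                n: table[:, i].astype(d).astype(np.float64)
                for i, (n, d) in enumerate(props)
            }
        else:
            raw = np.fromfile(fh, dtype=dtype, count=n_vertices)
            if raw.shape[0] < n_vertices:
                raise PLYFormatError(f"{path}: truncated binary vertex data")
            data = {n: raw[n].astype(np.float64) for n, _ in props}

    coords = np.column_stack([data["x"], data["y"], data["z"]])
    colors = np.column_stack(
        [data[color_cols["red"]], data[color_cols["green"]], data[color_cols["blue"]]]
    )
    # float colors on the unit scale -> canonical 0-255
    color_dtypes = {d for n, d in props if _COLOR_ALIASES.get(n)}
    if color_dtypes <= {"f4", "f8"} and colors.size and colors.max() <= 1.0:
        colors = colors * 255.0
    return ColoredPointCloud(coords, np.clip(colors, 0, 255), units_per_cm=units_per_cm)


def write_ply(cloud: ColoredPointCloud, path: str | Path, ascii_flag: bool = False) -> Path:
    """Write a colored point cloud to PLY (uchar colors, float32 coordinates).

    Returns the path written.  ``ascii_flag`` selects the ASCII dialect;
    otherwise binary-little-endian is used.  Coordinates are stored as
    float32, so the round trip is exact only to float32 precision.
    """
    path = Path(path)
    n = cloud.point_count
    fmt = "ascii" if ascii_flag else "binary_little_endian"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {n}\n"
        "property float x\n"
        "property float y\n"
        "property float z\n"
        "property uchar red\n"
        "property uchar green\n"
        "property uchar blue\n"
        "end_header\n"
    )
    coords = cloud.coords.astype(np.float32)
    colors = np.rint(cloud.colors).clip(0, 255).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if ascii_flag:
            for i in range(n):
                x, y, z = coords[i]
                r, g, b = colors[i]
                fh.write(f"{x:.9g} {y:.9g} {z:.9g} {r} {g} {b}\n".encode("ascii"))
        else:
            rec = np.empty(
                n,
                dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
                       ("red", "u1"), ("green", "u1"), ("blue", "u1")],
            )
            rec["x"], rec["y"], rec["z"] = coords[:, 0], coords[:, 1], coords[:, 2]
            rec["red"], rec["green"], rec["blue"] = colors[:, 0], colors[:, 1], colors[:, 2]
            rec.tofile(fh)
    return path
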