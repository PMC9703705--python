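"""Pipeline configuration: printed-method defaults in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Parameters of the full panicle-phenotyping pipeline.

    Defaults are the method's published operating point: HSV value floor
    0.15 for background masking, VARI threshold 0.1 for cluster selection,
    5-degree sweep step (36 projections), 10 axial slices.
    """

    h_range: tuple[float, float] = (0.0, 1.0)
    s_range: tuple[float, float] = (0.0, 1.0)
    v_range: tuple[float, float] = (0.15, 1.0)
    cluster_voxel_size: float | None = None  # None -> 2x median NN spacing
    vari_threshold: float = 0.1
    sweep_step_deg: float = 5.0
    n_slices: int = 10
    boundary_method: str = "alpha_shape"
    trait_voxel_size: float | None = None
    color_mode: str = "intensity"
    units_per_cm: float | None = None
    up_hint: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.vari_threshold is None or self.n_slices < 1:
            raise ValueError("invalid configuration")
        from .geometry import BOUNDARY_METHODS

        if self.boundary_method not in BOUNDARY_METHODS:
            raise ValueError(f"boundary_method must be one of {BOUNDARY_METHODS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("h_range", "s_range", "v_range", "up_hint"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def provenance(self, input_path: str | Path | None = None) -> dict:
        """Machine-readable run record: config, package version, input hash."""
        from . import __version__

        record = {"config": self.to_dict(), "version": __version__}
        if input_path is not None:
            import hashlib

            h = hashlib.sha256()
            with open(input_path, "rb") as fh:
                for chunk in iter(lambda: fh.read(1 << 20), b""):
                    h.update(chunk)
            record["input"] = str(input_path)
            record["input_sha256"] = h.hexdigest()
        return record

    def write_provenance(self, out_dir: str | Path, input_path=None) -> Path:
        path = Path(out_dir) / "provenance.json"
        path.write_text(json.dumps(self.provenance(input_path), indent=2))
        return path
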