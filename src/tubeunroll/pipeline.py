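"""End-to-end unrolling runs: configuration, orchestration, provenance.

``run_unroll`` ties the stages together: trace field lines on the key
slices, build internal contours, interpolate them vertically into
re-slicing surfaces, open/stretch them about the rotation axis and probe
the image stack.  Every output carries the full parameter set, so a run
can be reproduced from its sidecar plus the inputs.  The whole pipeline
is deterministic: identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fieldlines import FieldLineParams, trace_all
from .geometry import ContractError, normalize_contour, pair_boundaries
from .io import read_contours, read_stack, write_stack
from .mapping import CycloramaVolume, inverse_map, probe_volume
from .meshing import DepthGrid, ReslicingSurfaceSet, internal_contours, interpolate_sections

logger = logging.getLogger("tubeunroll")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All tunables of one unrolling run.

    Defaults mirror the documented murine-colon parameter set (I=200,
    w=15, delta=2 px, V_min=50 px^2, rigidity=1, m=20, C=30, K_max=75).
    """

    n_points: int = 200
    window: int = 15
    delta: float = 2.0
    rigidity: float = 1.0
    v_min: float = 50.0
    k_max: int = 75
    depth_levels: int = 30
    interp_interval: int = 20
    origin: tuple[float, float] | None = None
    interp: str = "bilinear"
    fill: float = 0.0
    reverse: bool = False
    clip_final: bool = True
    stack: str | None = None
    contours: str | None = None
    out: str | None = None
    verbosity: str = "info"

    def validate(self) -> None:
        try:
            self.field_params()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if self.depth_levels < 2:
            raise ConfigError("depth_levels C must be >= 2")
        if self.interp_interval < 1:
            raise ConfigError("interp_interval m must be >= 1")
        if self.interp not in ("bilinear", "nearest"):
            raise ConfigError("interp must be 'bilinear' or 'nearest'")
        if self.origin is not None and len(self.origin) != 2:
            raise ConfigError("origin must be an (x, y) pair")

    def field_params(self) -> FieldLineParams:
        return FieldLineParams(n_points=self.n_points, window=self.window,
                               delta=self.delta, rigidity=self.rigidity,
                               k_max=self.k_max, v_min=self.v_min)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["origin"] is not None:
            d["origin"] = list(d["origin"])
        return d


def load_config_file(path) -> RunConfig:
    """Parse a plain-text ``key = value`` config file (same keys as flags)."""
    kwargs: dict = {}
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in fields:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        if key == "origin":
            kwargs[key] = tuple(float(v) for v in value.split(","))
        elif key in ("reverse", "clip_final"):
            kwargs[key] = value.lower() in ("1", "true", "yes", "on")
        elif key in ("stack", "contours", "out", "interp", "verbosity"):
            kwargs[key] = value
        elif key in ("delta", "rigidity", "v_min", "fill"):
            kwargs[key] = float(value)
        else:
            kwargs[key] = int(value)
    return RunConfig(**kwargs)


def build_sections(raw_slices, config: RunConfig) -> dict:
    """Normalise and pair the raw boundary contours of each key slice."""
    sections = {}
    for h, inner_pts, outer_pts in raw_slices:
        inner = normalize_contour(inner_pts, config.n_points)
        outer = normalize_contour(outer_pts, config.n_points)
        sections[h] = pair_boundaries(inner, outer, slice_index=h)
    return sections


def build_surfaces(sections: dict, H: int, config: RunConfig):
    """Trace, contour and vertically interpolate; returns (surfaces, lines)."""
    grid = DepthGrid(C=config.depth_levels, m=config.interp_interval, H=H)
    missing = [h for h in grid.key_slices if h not in sections]
    if missing:
        raise ContractError(f"no boundary contours for key slices {missing}")
    params = config.field_params()
    key_contours = {}
    lines_by_slice = {}
    for h in sorted(sections):
        lines = trace_all(sections[h], params, clip_final=config.clip_final)
        lines_by_slice[h] = lines
        key_contours[h] = internal_contours(lines, sections[h],
                                            config.depth_levels, config.n_points)
    surfaces = interpolate_sections(key_contours, grid)
    return surfaces, lines_by_slice


def unroll(volume: np.ndarray, raw_slices, config: RunConfig) -> CycloramaVolume:
    """Unroll an in-memory stack given raw per-slice boundary contours."""
    config.validate()
    sections = build_sections(raw_slices, config)
    surfaces, lines = build_surfaces(sections, volume.shape[0], config)
    cyclo = probe_volume(volume, surfaces, origin=config.origin,
                         interp=config.interp, fill=config.fill,
                         reverse=config.reverse)
    cyclo.params["run_config"] = config.to_dict()
    cyclo.params["removed_lines"] = {
        str(h): config.n_points - len(lns) for h, lns in lines.items()
    }
    return cyclo


def run_unroll(config: RunConfig) -> CycloramaVolume:
    """File-to-file unrolling run; writes panorama TIFF, sidecar and log."""
    config.validate()
    if not config.stack or not config.contours:
        raise ConfigError("run_unroll needs stack and contours paths")
    volume = read_stack(config.stack)
    raw_slices = read_contours(config.contours)
    cyclo = unroll(volume, raw_slices, config)
    if config.out:
        out = Path(config.out)
        dtype = volume.dtype if np.issubdtype(volume.dtype, np.integer) else None
        cyclo.save_tiff(out, dtype=dtype)
        cyclo.save_sidecar(out.with_suffix(".map.npz"))
        with open(out.with_suffix(".params.json"), "w") as fh:
            json.dump(cyclo.params, fh, indent=2)
        logger.info("wrote %s (+ sidecar, params)", out)
    return cyclo


def run_invmap(sidecar_path, seeds, cube: int, out=None) -> np.ndarray:
    """Map panorama seed points back into a voxel mask.

    ``seeds`` is a path to a JSON file ``{"points": [[l, h, c], ...]}`` or
    an iterable of such triples.  The output mask has the original
    stack's dimensions (recorded in the sidecar) and is written as a
    multi-page binary TIFF when ``out`` is given.
    """
    source, header = CycloramaVolume.load_sidecar(sidecar_path)
    volume_shape = header["params"]["volume_shape"]
    if isinstance(seeds, (str, Path)):
        with open(seeds) as fh:
            seeds = json.load(fh)["points"]
    mask = inverse_map(seeds, source, volume_shape, cube=cube)
    if out is not None:
        write_stack(out, mask)
    return mask
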