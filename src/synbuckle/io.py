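"""Configuration files, mesh exports (OBJ / legacy VTK), traces and summaries.

Config files are YAML with strict keys (unknown keys are errors), lengths in
nm, energies in k_BT, times in calibrated milliseconds.  Every run directory
is self-describing: it receives a copy of the resolved config alongside the
trace CSV, pit-report JSON and mesh snapshots.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .dynamics import Event, StopCriteria
from .energy import ModelParams
from .errors import ConfigurationError
from .mesh import SurfaceMesh, mean_curvature
from .scenarios import ScenarioSpec, VesicleSpec


# -- mesh exports ----------------------------------------------------------------

def write_obj(mesh: SurfaceMesh, path):
    """Wavefront OBJ snapshot of the embedded surface (vertices in nm)."""
    path = Path(path)
    xyz = mesh.embedded_vertices()
    with path.open("w") as fh:
        fh.write("# synbuckle membrane snapshot (nm)\n")
        for x, y, z in xyz:
            fh.write(f"v {x:.6g} {y:.6g} {z:.6g}\n")
        for f in mesh.faces + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


def write_vtk(mesh: SurfaceMesh, path):
    """Legacy-VTK (ASCII) snapshot with per-vertex height and mean curvature
    and the per-face material label."""
    path = Path(path)
    xyz = mesh.embedded_vertices()
    omega = mean_curvature(mesh)
    nf = mesh.n_faces
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nsynbuckle membrane snapshot (nm)\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(xyz)} double\n")
        for x, y, z in xyz:
            fh.write(f"{x:.8g} {y:.8g} {z:.8g}\n")
        fh.write(f"POLYGONS {nf} {4 * nf}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        fh.write(f"POINT_DATA {len(xyz)}\n")
        fh.write("SCALARS height double 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(f"{v:.8g}" for v in mesh.height) + "\n")
        fh.write("SCALARS mean_curvature double 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(f"{v:.8g}" for v in omega) + "\n")
        fh.write(f"CELL_DATA {nf}\n")
        fh.write("SCALARS material_label int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(l)) for l in mesh.material_label) + "\n")


# -- scenario (de)serialization ---------------------------------------------------

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParams)}
_VESICLE_KEYS = {"center", "diameter", "apex_depth", "rim_radius"}
_EVENT_KEYS = {"kind", "time_ms", "depth_trigger_nm", "watch_vesicle", "uniform_kappa", "vesicle"}
_SPEC_KEYS = {"L", "w", "vesicles", "events", "params", "target_edge", "shape"}


def _check_keys(d: dict, allowed: set, where: str):
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) {sorted(unknown)} in {where}")


def vesicle_to_dict(v: VesicleSpec) -> dict:
    return {
        "center": [float(v.center[0]), float(v.center[1])],
        "diameter": v.diameter,
        "apex_depth": v.apex_depth,
        "rim_radius": v.rim_radius,
    }


def vesicle_from_dict(d: dict) -> VesicleSpec:
    _check_keys(d, _VESICLE_KEYS, "vesicle")
    if "center" not in d:
        raise ConfigurationError("vesicle requires key 'center'")
    d = dict(d)
    d["center"] = tuple(d["center"])
    return VesicleSpec(**d)


def event_to_dict(e: Event) -> dict:
    out = {"kind": e.kind}
    if e.time_ms is not None:
        out["time_ms"] = e.time_ms
    if e.depth_trigger_nm is not None:
        out["depth_trigger_nm"] = e.depth_trigger_nm
        out["watch_vesicle"] = e.watch_vesicle
    if e.uniform_kappa is not None:
        out["uniform_kappa"] = e.uniform_kappa
    if e.vesicle is not None:
        out["vesicle"] = vesicle_to_dict(e.vesicle)
    return out


def event_from_dict(d: dict) -> Event:
    _check_keys(d, _EVENT_KEYS, "event")
    d = dict(d)
    if "vesicle" in d and d["vesicle"] is not None:
        d["vesicle"] = vesicle_from_dict(d["vesicle"])
    if "uniform_kappa" not in d:
        d["uniform_kappa"] = None
    return Event(**d)


def spec_to_dict(spec: ScenarioSpec) -> dict:
    return {
        "L": spec.L,
        "w": spec.w,
        "target_edge": spec.target_edge,
        "shape": spec.shape,
        "vesicles": [vesicle_to_dict(v) for v in spec.vesicles],
        "events": [event_to_dict(e) for e in spec.events],
        "params": dataclasses.asdict(spec.params),
    }


def spec_from_dict(d: dict) -> ScenarioSpec:
    _check_keys(d, _SPEC_KEYS, "scenario")
    d = dict(d)
    if "params" in d:
        _check_keys(d["params"], _PARAM_KEYS, "params")
        d["params"] = ModelParams(**d["params"])
    d["vesicles"] = [vesicle_from_dict(v) for v in d.get("vesicles", [])]
    d["events"] = [event_from_dict(e) for e in d.get("events", [])]
    return ScenarioSpec(**d)


def save_spec(spec: ScenarioSpec, path):
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def load_spec(path) -> ScenarioSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


# -- run configuration -------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Scenario plus run controls; fully serializable, so a run is
    reproducible from its emitted config copy alone."""

    scenario: ScenarioSpec
    stop: StopCriteria = dataclasses.field(default_factory=StopCriteria)
    ms_per_time: float | None = None  # None -> package default calibration
    output_dir: str = "runs/out"
    snapshot_every_ms: float | None = None  # None -> final snapshot only

    def to_dict(self) -> dict:
        return {
            "scenario": spec_to_dict(self.scenario),
            "stop": dataclasses.asdict(self.stop),
            "ms_per_time": self.ms_per_time,
            "output_dir": self.output_dir,
            "snapshot_every_ms": self.snapshot_every_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, {"scenario", "stop", "ms_per_time", "output_dir", "snapshot_every_ms"}, "run config")
        if "scenario" not in d:
            raise ConfigurationError("run config requires key 'scenario'")
        stop = StopCriteria(**d["stop"]) if "stop" in d else StopCriteria()
        if "stop" in d:
            _check_keys(d["stop"], {"t_max_ms", "eps_E", "window"}, "stop")
        return cls(
            scenario=spec_from_dict(d["scenario"]),
            stop=stop,
            ms_per_time=d.get("ms_per_time"),
            output_dir=d.get("output_dir", "runs/out"),
            snapshot_every_ms=d.get("snapshot_every_ms"),
        )


def save_run_config(cfg: RunConfig, path):
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def load_run_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# -- summaries ---------------------------------------------------------------------

def write_json(obj, path):
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
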