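"""Run configuration: defaults, validation, serialization.

A run config is a plain nested mapping (YAML on disk). ``validate_config``
fills defaults (the protocol constants: seven b-values, the kinetic
constants, cohort sizes), rejects contradictions with field-path messages,
and returns a normalized :class:`RunConfig` that ``run_pipeline`` consumes.
"""
from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field

import yaml

from .asl import ASLParams
from .dwi import DEFAULT_BVALUES
from .errors import ConfigError
from .geometry import PhantomGeometry
from .synth import CohortConfig

_DEFAULTS: dict = {
    "seed": 0,
    "geometry": {"shape": [64, 64, 28], "voxel_size_mm": [1.8, 1.8, 4.0]},
    "synth": {
        "n_control": 32,
        "n_pd": 27,
        "coupling_rho": -0.312,
        "noise_sigma": 15.0,
        "d_sd_voxel": 0.0,
        "n_asl_pairs": 8,
        "asl_noise_sigma": 0.0005,
        "m0_blood": 1.0,
    },
    "dwi": {
        "bvalues": list(DEFAULT_BVALUES),
        "n_directions": 6,
        "model": "noise_modeled",
        "trace": "geometric",
    },
    "asl": {
        "enabled": True,
        "alpha": 0.8,
        "lambda_bbp": 0.9,
        "tau": 1800.0,
        "pld": 2000.0,
        "delta_t": 1240.0,
        "t1_blood": 1624.0,
        "t1_tissue": 2500.0,
        "slice_time": 0.0,
        "threshold": 10.0,
        "blood_water_factor": 1.0,
    },
    "stats": {
        "alpha_fdr": 0.10,
        "min_extent": 1,
        "combined_regression": False,
        "stratified_correlation": False,
    },
    "inputs": {  # optional pre-existing files; when set, generation is skipped
        "dwi": None, "bvals": None, "asl": None, "m0": None,
        "masks": None, "cohort": None,
    },
}


@dataclass
class RunConfig:
    """Normalized pipeline configuration."""

    raw: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULTS))

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def geometry(self) -> PhantomGeometry:
        g = self.raw["geometry"]
        return PhantomGeometry(shape=tuple(int(v) for v in g["shape"]),
                               voxel_size_mm=tuple(float(v) for v in g["voxel_size_mm"]))

    def asl_params(self) -> ASLParams:
        a = self.raw["asl"]
        return ASLParams(alpha=a["alpha"], lambda_bbp=a["lambda_bbp"], tau=a["tau"],
                         pld=a["pld"], delta_t=a["delta_t"], t1_blood=a["t1_blood"],
                         t1_tissue=a["t1_tissue"], slice_time=a["slice_time"])

    def cohort_config(self) -> CohortConfig:
        s = self.raw["synth"]
        return CohortConfig(
            n_control=int(s["n_control"]), n_pd=int(s["n_pd"]),
            coupling_rho=float(s["coupling_rho"]), seed=self.seed,
            noise_sigma=float(s["noise_sigma"]), d_sd_voxel=float(s["d_sd_voxel"]),
            bvalues=tuple(float(b) for b in self.raw["dwi"]["bvalues"]),
            n_directions=int(self.raw["dwi"]["n_directions"]),
            asl_params=self.asl_params(), n_asl_pairs=int(s["n_asl_pairs"]),
            asl_noise_sigma=float(s["asl_noise_sigma"]),
            m0_blood=float(s["m0_blood"]),
        )

    def to_dict(self) -> dict:
        return copy.deepcopy(self.raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)


def _merge(base: dict, override: dict, path: str, problems: list) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if key not in base:
            problems.append(f"{path}{key}: unknown field")
            continue
        if isinstance(base[key], dict) and key != "inputs":
            if not isinstance(val, dict):
                problems.append(f"{path}{key}: expected a mapping")
                continue
            out[key] = _merge(base[key], val, f"{path}{key}.", problems)
        elif key == "inputs":
            out[key] = _merge(base[key], val or {}, f"{path}{key}.", problems)
        else:
            out[key] = val
    return out


def validate_config(config: dict | RunConfig | None) -> RunConfig:
    """Normalize a (possibly partial) config; raise ConfigError listing problems."""
    if isinstance(config, RunConfig):
        config = config.to_dict()
    problems: list[str] = []
    merged = _merge(_DEFAULTS, config or {}, "", problems)

    dwi = merged["dwi"]
    bvals = list(dwi["bvalues"])
    distinct = len(set(float(b) for b in bvals))
    if any(float(b) < 0 for b in bvals):
        problems.append("dwi.bvalues: b-values must be non-negative")
    if distinct < 2:
        problems.append("dwi.bvalues: at least 2 distinct b-values required")
    if dwi["model"] not in ("standard", "noise_modeled"):
        problems.append(f"dwi.model: unknown model {dwi['model']!r}")
    if dwi["model"] == "noise_modeled" and distinct < 3:
        problems.append("dwi.model: noise_modeled fits 3 parameters and needs "
                        f">= 3 distinct b-values (got {distinct})")
    if dwi["trace"] not in ("geometric", "arithmetic"):
        problems.append(f"dwi.trace: unknown trace convention {dwi['trace']!r}")
    if int(dwi["n_directions"]) < 1:
        problems.append("dwi.n_directions: must be >= 1")

    a = merged["asl"]
    if not (0.0 < float(a["alpha"]) <= 1.0):
        problems.append(f"asl.alpha: must be in (0, 1], got {a['alpha']}")
    for key in ("lambda_bbp", "tau", "pld", "delta_t", "t1_blood", "t1_tissue"):
        if float(a[key]) <= 0:
            problems.append(f"asl.{key}: must be positive")
    if float(a["slice_time"]) < 0:
        problems.append("asl.slice_time: must be non-negative")
    if float(a["threshold"]) < 0:
        problems.append("asl.threshold: must be non-negative")

    s = merged["synth"]
    if int(s["n_control"]) < 0 or int(s["n_pd"]) < 0:
        problems.append("synth.n_control/n_pd: must be non-negative")
    if abs(float(s["coupling_rho"])) > 1:
        problems.append(f"synth.coupling_rho: must be in [-1, 1], got {s['coupling_rho']}")
    if float(s["noise_sigma"]) < 0:
        problems.append("synth.noise_sigma: must be non-negative")
    if int(s["n_asl_pairs"]) < 1:
        problems.append("synth.n_asl_pairs: must be >= 1")

    st = merged["stats"]
    if not (0.0 < float(st["alpha_fdr"]) < 1.0):
        problems.append(f"stats.alpha_fdr: must be in (0, 1), got {st['alpha_fdr']}")
    if int(st["min_extent"]) < 1:
        problems.append("stats.min_extent: must be >= 1")

    g = merged["geometry"]
    if len(g["shape"]) != 3 or any(int(v) < 1 for v in g["shape"]):
        problems.append("geometry.shape: three positive integers required")
    if any(float(v) <= 0 for v in g["voxel_size_mm"]):
        problems.append("geometry.voxel_size_mm: must be strictly positive")

    if problems:
        raise ConfigError(problems)
    return RunConfig(raw=merged)


def load_config(path: str | None) -> RunConfig:
    if path is None:
        return validate_config({})
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return validate_config(data)
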