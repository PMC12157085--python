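"""Configuration files, raster/rate round-tripping, and fixtures.

All artifacts are plain text: rasters and rate trajectories are CSV with a
JSON sidecar holding the metadata (sizes, gain, seeds, a hash of the weight
statistics, the input schedule) plus an integrity checksum of the data file.
Configs are YAML (JSON being a subset).  Timestep indexing is 0-based
everywhere.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import WeightSpec, build_preset
from .core import InputSchedule, ModelConfig, SpikeRaster

__all__ = [
    "RunConfig",
    "load_config",
    "spec_hash",
    "write_raster",
    "read_raster",
    "write_rates",
    "read_rates",
    "IntegrityError",
    "Fixture",
    "make_fixture",
    "FIXTURE_NAMES",
]


class IntegrityError(RuntimeError):
    """A data file does not match its sidecar metadata."""


def spec_hash(spec: WeightSpec) -> str:
    h = hashlib.sha256()
    h.update(spec.mean_matrix.tobytes())
    h.update(spec.var_matrix.tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_MODEL_KEYS = {"N", "D", "g", "T", "seed"}
_TOP_KEYS = {"model", "weights", "input", "record", "analysis", "output_dir", "seeds"}
_ANALYSIS_KEYS = {"window", "threshold_factor", "max_lag", "min_isis"}


@dataclass
class RunConfig:
    """Validated contents of a run configuration file."""

    model: ModelConfig
    spec: WeightSpec
    schedule: InputSchedule
    record: str = "rates"
    analysis: dict = field(default_factory=dict)
    output_dir: str = "."
    seeds: dict = field(default_factory=dict)
    weights_section: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "model": {
                "N": self.model.N,
                "D": self.model.D,
                "g": "inf" if math.isinf(self.model.g) else self.model.g,
                "T": self.model.T,
                "seed": self.model.seed,
            },
            "weights": self.weights_section,
            "input": self.schedule.to_jsonable(),
            "record": self.record,
            "analysis": self.analysis,
            "output_dir": self.output_dir,
            "seeds": self.seeds,
        }


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def _parse_gain(g) -> float:
    if isinstance(g, str):
        if g.lower() in ("inf", "infinity"):
            return math.inf
        raise ValueError(f"invalid gain {g!r}; use a positive number or 'inf'")
    return float(g)


def parse_config(data: dict) -> RunConfig:
    """Validate a configuration mapping; unknown keys are rejected by name."""
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    _reject_unknown(data, _TOP_KEYS, "config")
    model_raw = data.get("model")
    if not isinstance(model_raw, dict):
        raise ValueError("config requires a 'model' section")
    _reject_unknown(model_raw, _MODEL_KEYS, "model")
    model = ModelConfig(
        N=int(model_raw["N"]),
        D=int(model_raw["D"]),
        g=_parse_gain(model_raw.get("g", "inf")),
        T=int(model_raw.get("T", 1000)),
        seed=int(model_raw.get("seed", 0)),
    )

    wsec = dict(data.get("weights", {"preset": "unstructured", "D": model.D}))
    if "mean_matrix" in wsec or "var_matrix" in wsec:
        _reject_unknown(wsec, {"mean_matrix", "var_matrix"}, "weights")
        spec = WeightSpec(
            np.asarray(wsec["mean_matrix"], float),
            np.asarray(wsec["var_matrix"], float),
        )
    else:
        if "preset" not in wsec:
            raise ValueError("weights section needs a 'preset' or explicit matrices")
        params = {k: v for k, v in wsec.items() if k != "preset"}
        params.setdefault("D", model.D)
        spec = build_preset(wsec["preset"], **params)
    if spec.D != model.D:
        raise ValueError(
            f"weights dimension {spec.D} does not match model.D={model.D}"
        )

    schedule = InputSchedule.from_jsonable(data.get("input", []), D=model.D)
    for e in schedule.epochs:
        if not (0 <= e.t_start < e.t_end <= model.T):
            raise ValueError(
                f"epoch [{e.t_start}, {e.t_end}) outside simulation window [0, {model.T})"
            )

    record = data.get("record", "rates")
    if record not in ("rates", "raster", "activations"):
        raise ValueError(f"invalid record mode {record!r}")
    analysis = dict(data.get("analysis", {}))
    _reject_unknown(analysis, _ANALYSIS_KEYS, "analysis")
    seeds = dict(data.get("seeds", {}))
    for k, v in seeds.items():
        if not isinstance(v, int):
            raise ValueError(f"seed override {k!r} must be an integer")
    return RunConfig(
        model=model,
        spec=spec,
        schedule=schedule,
        record=record,
        analysis=analysis,
        output_dir=str(data.get("output_dir", ".")),
        seeds=seeds,
        weights_section=wsec,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_config(data)


# ---------------------------------------------------------------------------
# raster / rates round trip
# ---------------------------------------------------------------------------

def _file_sha(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_raster(
    raster: SpikeRaster,
    path: str | Path,
    spec: WeightSpec | None = None,
    schedule: InputSchedule | None = None,
) -> Path:
    """Write spike events as CSV (t,unit,tuning) plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"t": raster.t, "unit": raster.unit, "tuning": raster.tuning})
    df.to_csv(path, index=False)
    meta = {
        "kind": "raster",
        "N": raster.N,
        "D": raster.D,
        "T": raster.T,
        "g": "inf" if math.isinf(raster.g) else raster.g,
        "seed": raster.seed,
        "n_events": len(raster),
        "spec_hash": spec_hash(spec) if spec is not None else None,
        "schedule": schedule.to_jsonable() if schedule is not None else None,
        "sha256": _file_sha(path),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_raster(path: str | Path) -> SpikeRaster:
    """Read a raster CSV, verifying the sidecar checksum and event count."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise IntegrityError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    if _file_sha(path) != meta["sha256"]:
        raise IntegrityError(f"checksum mismatch for {path}")
    df = pd.read_csv(path)
    if len(df) != meta["n_events"]:
        raise IntegrityError(
            f"{path}: expected {meta['n_events']} events, found {len(df)}"
        )
    g = meta["g"]
    return SpikeRaster(
        df["t"].to_numpy(),
        df["unit"].to_numpy(),
        df["tuning"].to_numpy(),
        N=meta["N"],
        D=meta["D"],
        T=meta["T"],
        seed=meta["seed"],
        g=math.inf if g == "inf" else float(g),
    )


def write_rates(rates: np.ndarray, path: str | Path, meta: dict | None = None) -> Path:
    """Write a (T, D) rate trajectory as CSV t,r_0..r_{D-1} (full precision)."""
    rates = np.asarray(rates, dtype=float)
    path = Path(path)
    D = rates.shape[1]
    df = pd.DataFrame(rates, columns=[f"r_{d}" for d in range(D)])
    df.insert(0, "t", np.arange(rates.shape[0]))
    df.to_csv(path, index=False, float_format="%.17g")
    out_meta = {"kind": "rates", "T": rates.shape[0], "D": D}
    out_meta.update(meta or {})
    out_meta["sha256"] = _file_sha(path)
    _sidecar(path).write_text(json.dumps(out_meta, indent=1))
    return path


def read_rates(path: str | Path) -> np.ndarray:
    """Read a rate-trajectory CSV, verifying the sidecar checksum."""
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise IntegrityError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    if _file_sha(path) != meta["sha256"]:
        raise IntegrityError(f"checksum mismatch for {path}")
    df = pd.read_csv(path)
    rates = df[[c for c in df.columns if c.startswith("r_")]].to_numpy()
    if rates.shape != (meta["T"], meta["D"]):
        raise IntegrityError(f"{path}: shape mismatch vs sidecar")
    return rates


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """Deterministically regenerable test payload."""

    name: str
    seed: int
    params: dict
    payload: dict


def _fixture_hand_net_2x2(seed: int, **_) -> dict:
    # N=2 units, D=2 tunings, explicit weights and a hand-summed input field
    J = np.zeros((2, 2, 2, 2))  # [d, d', i, j]
    J[0, 0] = [[0.5, -0.25], [1.0, 0.0]]
    J[0, 1] = [[0.1, 0.2], [-0.3, 0.4]]
    J[1, 0] = [[-0.5, 0.6], [0.7, -0.8]]
    J[1, 1] = [[0.0, 1.5], [0.25, -0.75]]
    y_prev = np.array([[1.0, 0.0], [0.25, 0.75]])
    # x_id = sum_{d', j} J[d, d', i, j] * y_prev[j, d']
    x = np.einsum("dcij,jc->id", J, y_prev)
    return {"J": J, "y_prev": y_prev, "x_expected": x}


def _fixture_bernoulli_train(seed: int, p: float = 0.05, T: int = 200_000) -> dict:
    from .rng import stream

    rng = stream(seed, "fixture-bernoulli")
    spikes = np.flatnonzero(rng.random(T) < p)
    return {"p": p, "T": T, "spike_times": spikes}


def _fixture_rotating_bump(
    seed: int, D: int = 16, speed: float = 1.0, T: int = 200, width: float = 1.5
) -> dict:
    # von Mises-shaped bump whose center advances `speed` populations/step
    theta = -np.pi + 2.0 * np.pi * np.arange(D) / D
    traj = np.empty((T, D))
    for t in range(T):
        center = -np.pi + 2.0 * np.pi * ((speed * t) % D) / D
        prof = np.exp(np.cos(theta - center) / width**2)
        traj[t] = prof / prof.sum()
    return {"D": D, "speed": speed, "T": T, "rates": traj}


def _fixture_hand_raster_3x4(seed: int, **_) -> dict:
    # N=3 units, D=2 tunings, T=4: winners enumerated by hand
    winners = np.array(
        [
            [0, 1, 0],  # t=0
            [0, 0, 1],  # t=1
            [1, 1, 1],  # t=2
            [0, 1, 0],  # t=3
        ]
    )
    T, N = winners.shape
    t = np.repeat(np.arange(T), N)
    unit = np.tile(np.arange(N), T)
    raster = SpikeRaster(t, unit, winners.reshape(-1), N=N, D=2, T=T, seed=seed)
    pop_rates = np.array(
        [[2 / 3, 1 / 3], [2 / 3, 1 / 3], [0.0, 1.0], [2 / 3, 1 / 3]]
    )
    neuron_rates = {  # (unit, tuning) -> spikes / T
        (0, 0): 3 / 4, (0, 1): 1 / 4,
        (1, 0): 1 / 4, (1, 1): 3 / 4,
        (2, 0): 2 / 4, (2, 1): 2 / 4,
    }
    return {"raster": raster, "pop_rates": pop_rates, "neuron_rates": neuron_rates}


_FIXTURES = {
    "hand-net-2x2": _fixture_hand_net_2x2,
    "bernoulli-train": _fixture_bernoulli_train,
    "rotating-bump": _fixture_rotating_bump,
    "hand-raster-3x4": _fixture_hand_raster_3x4,
}
FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str, seed: int = 0, **params) -> Fixture:
    """Generate a named fixture; identical (name, seed, params) are
    bit-identical on regeneration."""
    try:
        fn = _FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}") from None
    return Fixture(name=name, seed=seed, params=params, payload=fn(seed, **params))
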