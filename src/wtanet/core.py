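"""Microscopic network of winner-take-all units.

The network consists of N units, each holding D neurons with distinct
tunings.  At every discrete timestep (Delta t = 1) each neuron d in unit i
receives the input

    x_id(t) = sum_{d'} sum_j J_ij^{dd'} y_jd'(t-1) + u_id(t)

and the unit's activation vector is updated through a softmax with gain g,

    y_i(t) = Softmax(g x_i(t)),

which in the limit g -> infinity becomes a hard winner-take-all: exactly one
neuron per unit is active (a "spike") at each step.  The quenched weights
J_ij^{dd'} are i.i.d. Gaussian within each tuning block (d, d'), with mean
mu_J(d,d') * D/N and variance sigma_J^2(d,d') * D/N.

Two weight representations are provided.  ``dense`` materializes the full
(N*D) x (N*D) matrix.  ``blockwise`` stores a single N x N standard-normal
base block and reconstructs block (d, d') on the fly as a quenched random
row-and-column permutation of the base block, scaled and shifted to the
block's law - an O(N^2)-memory scheme for networks whose dense tensor would
not fit in memory.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .connectivity import WeightSpec
from .rng import stream

__all__ = [
    "ModelConfig",
    "InputSchedule",
    "SpikeRaster",
    "WeightTensor",
    "SimulationResult",
    "sample_weights",
    "softmax_activation",
    "hard_wta",
    "compute_inputs",
    "draw_external",
    "step_full",
    "simulate_full",
    "DENSE_COLUMN_CAP",
]

#: Dense weight storage is refused above this many columns (= N * D); use
#: blockwise mode instead.  The cap is an argument to :func:`sample_weights`.
DENSE_COLUMN_CAP = 20_000


@dataclass(frozen=True)
class ModelConfig:
    """Size, gain, duration and seed of a full-network simulation.

    ``g=math.inf`` selects the hard-WTA (spiking) regime.
    """

    N: int
    D: int
    g: float
    T: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.D < 2:
            raise ValueError("D must be >= 2")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not (self.g > 0):
            raise ValueError("g must be positive (math.inf for hard WTA)")

    @property
    def hard(self) -> bool:
        return math.isinf(self.g)


@dataclass(frozen=True)
class Epoch:
    """Half-open input epoch [t_start, t_end) with per-tuning moments."""

    t_start: int
    t_end: int
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        u = np.atleast_1d(np.asarray(self.u, dtype=float))
        v = np.atleast_1d(np.asarray(self.v, dtype=float))
        if u.shape != v.shape:
            raise ValueError("u and v must have the same length D")
        if np.any(v < 0):
            raise ValueError("input variances must be nonnegative")
        if self.t_end <= self.t_start:
            raise ValueError("epoch must satisfy t_start < t_end")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)


class InputSchedule:
    """Piecewise-constant external-input moments over time.

    Each epoch supplies a length-D vector of per-tuning input means u_d and
    nonnegative variances v_d over the half-open window [t_start, t_end)
    (0-based timesteps).  Outside every epoch the input is identically zero.
    Overlapping epochs add.
    """

    def __init__(self, epochs: list[Epoch] | None = None, D: int | None = None):
        self.epochs = list(epochs or [])
        if D is None and self.epochs:
            D = self.epochs[0].u.size
        self.D = D
        for e in self.epochs:
            if e.u.size != self.D:
                raise ValueError("all epochs must share the same D")

    @classmethod
    def empty(cls, D: int) -> "InputSchedule":
        return cls([], D=D)

    @classmethod
    def single(cls, t_start: int, t_end: int, u, v=None) -> "InputSchedule":
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.zeros_like(u) if v is None else np.asarray(v, dtype=float)
        return cls([Epoch(t_start, t_end, u, v)])

    def moments_at(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (u, v) at timestep t; zeros outside all epochs."""
        if self.D is None:
            raise ValueError("schedule has no dimension; use empty(D)")
        u = np.zeros(self.D)
        v = np.zeros(self.D)
        for e in self.epochs:
            if e.t_start <= t < e.t_end:
                u += e.u
                v += e.v
        return u, v

    def to_jsonable(self) -> list[dict]:
        return [
            {
                "t_start": int(e.t_start),
                "t_end": int(e.t_end),
                "u": e.u.tolist(),
                "v": e.v.tolist(),
            }
            for e in self.epochs
        ]

    @classmethod
    def from_jsonable(cls, data: list[dict], D: int | None = None) -> "InputSchedule":
        return cls(
            [Epoch(d["t_start"], d["t_end"], d["u"], d["v"]) for d in data], D=D
        )


@dataclass
class SpikeRaster:
    """Event list of a hard-WTA simulation: one spike per unit per step."""

    t: np.ndarray
    unit: np.ndarray
    tuning: np.ndarray
    N: int
    D: int
    T: int
    seed: int = 0
    g: float = math.inf

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.unit = np.asarray(self.unit, dtype=np.int64)
        self.tuning = np.asarray(self.tuning, dtype=np.int64)
        if not (self.t.shape == self.unit.shape == self.tuning.shape):
            raise ValueError("event columns must have equal length")
        if self.t.size and (self.unit.min() < 0 or self.unit.max() >= self.N):
            raise ValueError("unit index out of range")
        if self.t.size and (self.tuning.min() < 0 or self.tuning.max() >= self.D):
            raise ValueError("tuning index out of range")

    def __len__(self) -> int:
        return self.t.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeRaster):
            return NotImplemented
        return (
            (self.N, self.D, self.T, self.seed) == (other.N, other.D, other.T, other.seed)
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.unit, other.unit)
            and np.array_equal(self.tuning, other.tuning)
        )

    def spike_times(self, unit: int, tuning: int | None = None) -> np.ndarray:
        """Sorted spike times of one neuron (unit, tuning) or whole unit."""
        mask = self.unit == unit
        if tuning is not None:
            mask &= self.tuning == tuning
        return np.sort(self.t[mask])


class WeightTensor:
    """Quenched connectivity in dense or blockwise representation.

    Dense mode stores the flat (N*D) x (N*D) matrix with row/column index
    d * N + i, so that block (d, d') is ``flat[d*N:(d+1)*N, d'*N:(d'+1)*N]``
    with entry [i, j] the weight from neuron (j, d') onto neuron (i, d).

    Blockwise mode stores one N x N standard-normal base block Z0 and, per
    block (d, d'), a quenched random row and column permutation derived from
    (seed, d, d'); block (d, d') is then
    ``mu*D/N + sqrt(var*D/N) * Z0[rowperm][:, colperm]``.
    This reproduces the dense per-block first and second moments while
    holding only O(N^2) state.
    """

    def __init__(self, spec: WeightSpec, N: int, seed: int, mode: str):
        self.spec = spec
        self.N = int(N)
        self.D = spec.D
        self.seed = int(seed)
        self.mode = mode
        self._perm_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        if mode == "dense":
            ND = self.N * self.D
            rng = stream(seed, "weights")
            # Fortran order: column slices are contiguous, which makes the
            # winner-gather in the hard-WTA step cache-friendly.
            flat = np.empty((ND, ND), order="F")
            scale = self.D / self.N
            for d in range(self.D):
                for dp in range(self.D):
                    mu = spec.mean_matrix[d, dp] * scale
                    sd = math.sqrt(spec.var_matrix[d, dp] * scale)
                    block = rng.standard_normal((self.N, self.N)) * sd + mu
                    flat[d * self.N : (d + 1) * self.N, dp * self.N : (dp + 1) * self.N] = block
            self.flat = flat
        elif mode == "blockwise":
            self.Z0 = stream(seed, "weights-base").standard_normal((self.N, self.N))
        else:
            raise ValueError(f"unknown weight mode {mode!r}")

    # -- blockwise helpers -------------------------------------------------
    def _perms(self, d: int, dp: int) -> tuple[np.ndarray, np.ndarray]:
        key = (d, dp)
        if key not in self._perm_cache:
            g = stream(self.seed, "weights-perm", d, dp)
            self._perm_cache[key] = (g.permutation(self.N), g.permutation(self.N))
        return self._perm_cache[key]

    def block(self, d: int, dp: int) -> np.ndarray:
        """Materialize block (d, d') as an N x N array."""
        scale = self.D / self.N
        mu = self.spec.mean_matrix[d, dp] * scale
        sd = math.sqrt(self.spec.var_matrix[d, dp] * scale)
        if self.mode == "dense":
            return self.flat[d * self.N : (d + 1) * self.N, dp * self.N : (dp + 1) * self.N]
        rp, cp = self._perms(d, dp)
        return mu + sd * self.Z0[np.ix_(rp, cp)]

    def to_dense(self, column_cap: int = DENSE_COLUMN_CAP) -> "WeightTensor":
        """Materialize a blockwise tensor as a dense one (same weights)."""
        if self.mode == "dense":
            return self
        _check_dense_cap(self.N, self.D, column_cap)
        out = object.__new__(WeightTensor)
        out.spec, out.N, out.D, out.seed = self.spec, self.N, self.D, self.seed
        out.mode = "dense"
        out._perm_cache = {}
        ND = self.N * self.D
        flat = np.empty((ND, ND))
        for d in range(self.D):
            for dp in range(self.D):
                flat[d * self.N : (d + 1) * self.N, dp * self.N : (dp + 1) * self.N] = self.block(d, dp)
        out.flat = flat
        return out


def _check_dense_cap(N: int, D: int, column_cap: int) -> None:
    if N * D > column_cap:
        raise MemoryError(
            f"dense weights need {N * D} columns > cap {column_cap}; "
            "use mode='blockwise'"
        )


def sample_weights(
    spec: WeightSpec,
    N: int,
    seed: int,
    mode: str = "dense",
    column_cap: int = DENSE_COLUMN_CAP,
) -> WeightTensor:
    """Draw the quenched connectivity tensor for ``spec`` at size N.

    Entries of block (d, d') are i.i.d. Normal(mu_J(d,d') * D/N,
    sigma_J^2(d,d') * D/N).  Identical (seed, mode) gives a bit-identical
    tensor.  Dense mode refuses N * D > ``column_cap`` columns.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if mode == "dense":
        _check_dense_cap(N, spec.D, column_cap)
    return WeightTensor(spec, N, seed, mode)


def softmax_activation(x: np.ndarray, g: float) -> np.ndarray:
    """Row-wise stable softmax of g*x; rows sum to 1.

    Accepts a single length-D vector or an (N, D) array.
    """
    if not np.isfinite(g) or g <= 0:
        raise ValueError("g must be finite and positive; use hard_wta for g=inf")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("inputs must be finite")
    z = g * x
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def hard_wta(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One-hot vector at an argmax of x; ties broken uniformly via ``rng``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("inputs must be finite")
    winners = np.flatnonzero(x == x.max())
    w = winners[0] if winners.size == 1 else rng.choice(winners)
    out = np.zeros(x.size)
    out[w] = 1.0
    return out


def _hard_winners(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise argmax with uniform random tie-breaks; x is (N, D)."""
    w = np.argmax(x, axis=1)
    mx = x[np.arange(x.shape[0]), w]
    tie_rows = np.flatnonzero((x == mx[:, None]).sum(axis=1) > 1)
    for i in tie_rows:
        w[i] = rng.choice(np.flatnonzero(x[i] == mx[i]))
    return w


def compute_inputs(
    y_prev: np.ndarray, W: WeightTensor, ext: np.ndarray | None = None
) -> np.ndarray:
    """Net input field x_id = sum_{d', j} J_ij^{dd'} y_jd' + ext_id.

    ``y_prev`` and the returned array are (N, D).  Dense and blockwise
    representations of the same realized weights agree to ~1e-9 relative.
    """
    N, D = W.N, W.D
    y_prev = np.asarray(y_prev, dtype=float)
    if y_prev.shape != (N, D):
        raise ValueError(f"y_prev must have shape {(N, D)}")
    if W.mode == "dense":
        y_flat = y_prev.T.reshape(-1)  # index d*N + j
        x_flat = W.flat @ y_flat
        x = x_flat.reshape(D, N).T
    else:
        x = np.zeros((N, D))
        scale = D / N
        colsum = y_prev.sum(axis=0)  # total activity per tuning
        # mean part: constant across units within a block row
        x += (W.spec.mean_matrix * scale) @ colsum
        # fluctuation part: batched base-block matvecs, then row permutations
        blocks = [
            (d, dp)
            for d in range(D)
            for dp in range(D)
            if W.spec.var_matrix[d, dp] > 0
        ]
        if blocks:
            V = np.zeros((N, len(blocks)))
            for b, (d, dp) in enumerate(blocks):
                _, cp = W._perms(d, dp)
                V[cp, b] = y_prev[:, dp]
            G = W.Z0 @ V
            for b, (d, dp) in enumerate(blocks):
                rp, _ = W._perms(d, dp)
                sd = math.sqrt(W.spec.var_matrix[d, dp] * scale)
                x[:, d] += sd * G[rp, b]
    if ext is not None:
        ext = np.asarray(ext, dtype=float)
        if ext.shape != (N, D):
            raise ValueError(f"ext must have shape {(N, D)}")
        x = x + ext
    return x


def _winner_inputs(winners: np.ndarray, W: WeightTensor) -> np.ndarray:
    """compute_inputs specialized to one-hot states given winner indices."""
    N, D = W.N, W.D
    if W.mode == "dense":
        cols = winners * N + np.arange(N)
        x_flat = W.flat[:, cols].sum(axis=1)
        return x_flat.reshape(D, N).T
    y = np.zeros((N, D))
    y[np.arange(N), winners] = 1.0
    return compute_inputs(y, W)


def draw_external(
    schedule: InputSchedule, t: int, N: int, rng: np.random.Generator
) -> np.ndarray:
    """Realize the external input at step t: entry (i, d) ~ N(u_d, v_d).

    Zero-variance columns are deterministically u_d; with an empty schedule
    the array is exactly zero and no random numbers are consumed.
    """
    u, v = schedule.moments_at(t)
    D = u.size
    ext = np.tile(u, (N, 1))
    nz = np.flatnonzero(v > 0)
    if nz.size:
        ext[:, nz] += rng.standard_normal((N, nz.size)) * np.sqrt(v[nz])
    return ext


def step_full(
    y_prev: np.ndarray,
    W: WeightTensor,
    ext: np.ndarray | None,
    g: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One update of the full network: inputs, then softmax or hard WTA.

    ``rng`` is the tie-break stream, required only at g = inf.
    """
    x = compute_inputs(y_prev, W, ext)
    if math.isinf(g):
        if rng is None:
            raise ValueError("hard WTA requires a tie-break rng")
        winners = _hard_winners(x, rng)
        y = np.zeros_like(x)
        y[np.arange(x.shape[0]), winners] = 1.0
        return y
    return softmax_activation(x, g)


@dataclass
class SimulationResult:
    """Trajectory of a full-network simulation.

    ``rates`` is the (T, D) array of per-step population rates: at g = inf
    the fraction of units whose winner has tuning d; at finite g the column
    means of the activation matrix.  ``raster`` and ``activations`` are
    filled according to the record mode.
    """

    config: ModelConfig
    rates: np.ndarray
    raster: SpikeRaster | None = None
    activations: np.ndarray | None = None
    final_state: np.ndarray | None = None


def initial_state(config: ModelConfig) -> np.ndarray:
    """Initial activation matrix.

    At g = inf each unit's initial winner is drawn uniformly over the D
    tunings from the seeded "init" stream; at finite g every row starts at
    the uniform vector 1/D.
    """
    if config.hard:
        rng = stream(config.seed, "init")
        w = rng.integers(0, config.D, size=config.N)
        y = np.zeros((config.N, config.D))
        y[np.arange(config.N), w] = 1.0
        return y
    return np.full((config.N, config.D), 1.0 / config.D)


def simulate_full(
    config: ModelConfig,
    spec: WeightSpec,
    schedule: InputSchedule | None = None,
    record: str = "rates",
    mode: str | None = None,
    W: WeightTensor | None = None,
    column_cap: int = DENSE_COLUMN_CAP,
) -> SimulationResult:
    """Simulate the full network for T steps.

    record : {"rates", "raster", "activations"}
        "raster" (g = inf only) additionally collects the spike events;
        "activations" additionally stores the full (T, N, D) trajectory.
    mode : weight representation; defaults to dense when N*D fits the
        column cap and blockwise otherwise.
    W : optionally reuse a pre-sampled tensor (must match spec and N).
    """
    if record not in ("rates", "raster", "activations"):
        raise ValueError(f"unknown record mode {record!r}")
    if record == "raster" and not config.hard:
        raise ValueError("raster recording requires g = inf")
    if spec.D != config.D:
        raise ValueError("spec dimension does not match config.D")
    if schedule is None:
        schedule = InputSchedule.empty(config.D)
    if W is None:
        if mode is None:
            mode = "dense" if config.N * config.D <= column_cap else "blockwise"
        W = sample_weights(spec, config.N, config.seed, mode, column_cap=column_cap)
    ext_rng = stream(config.seed, "external")
    tie_rng = stream(config.seed, "ties")
    has_input = bool(schedule.epochs)

    y = initial_state(config)
    N, D, T = config.N, config.D, config.T
    rates = np.empty((T, D))
    events_t, events_u, events_d = [], [], []
    acts = np.empty((T, N, D)) if record == "activations" else None
    arangeN = np.arange(N)
    for t in range(T):
        ext = draw_external(schedule, t, N, ext_rng) if has_input else None
        if config.hard:
            if W.mode == "dense" and ext is None:
                winners_prev = np.argmax(y, axis=1)
                x = _winner_inputs(winners_prev, W)
            else:
                x = compute_inputs(y, W, ext)
            winners = _hard_winners(x, tie_rng)
            y = np.zeros((N, D))
            y[arangeN, winners] = 1.0
            rates[t] = np.bincount(winners, minlength=D) / N
            if record == "raster":
                events_t.append(np.full(N, t, dtype=np.int64))
                events_u.append(arangeN.astype(np.int64))
                events_d.append(winners.astype(np.int64))
        else:
            y = step_full(y, W, ext, config.g)
            rates[t] = y.mean(axis=0)
        if acts is not None:
            acts[t] = y

    raster = None
    if record == "raster":
        raster = SpikeRaster(
            np.concatenate(events_t),
            np.concatenate(events_u),
            np.concatenate(events_d),
            N=N,
            D=D,
            T=T,
            seed=config.seed,
            g=config.g,
        )
    return SimulationResult(
        config=config, rates=rates, raster=raster, activations=acts, final_state=y
    )
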