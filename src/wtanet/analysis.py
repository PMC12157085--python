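"""Derived statistics and diagnostics.

Interspike-interval irregularity (CV and the local, nonstationarity-robust
CV2), raster-derived rates, autocovariance, active-population counts and
their information content, ring-sequence metrics (circular mean, propagation
speed), microscopic perturbations, and the perturbation-growth chaos test
with bisection estimation of the critical gain.

Spike-time convention: a spike at step t is the event y_id(t) = 1; ISIs are
differences of integer step indices, so the minimum ISI is 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .connectivity import WeightSpec
from .core import (
    InputSchedule,
    ModelConfig,
    SpikeRaster,
    WeightTensor,
    compute_inputs,
    draw_external,
    initial_state,
    sample_weights,
    softmax_activation,
    _hard_winners,
)
from .rng import spawn_seeds, stream

__all__ = [
    "isis",
    "isi_cv",
    "isi_cv2",
    "rates_from_raster",
    "spike_train_stats",
    "autocovariance",
    "ActivePopulations",
    "active_populations",
    "RingGeometry",
    "circular_mean",
    "sequence_speed",
    "perturb_swap",
    "state_distance",
    "ChaosVerdict",
    "chaos_test",
    "critical_gain",
]

#: Neurons with fewer ISIs than this are flagged as undersampled in
#: population summaries (rare spikers bias the CV estimators).
MIN_ISIS = 10


# ---------------------------------------------------------------------------
# interspike-interval statistics
# ---------------------------------------------------------------------------

def isis(train: np.ndarray) -> np.ndarray:
    """Interspike intervals of a sorted spike-time array (< 2 spikes -> empty)."""
    train = np.asarray(train)
    if train.size < 2:
        return np.array([], dtype=train.dtype if train.size else np.int64)
    if np.any(np.diff(train) <= 0):
        raise ValueError("spike times must be strictly increasing")
    return np.diff(train)


def isi_cv(intervals: np.ndarray) -> float:
    """Coefficient of variation of ISIs (population std / mean).

    Near-unity CV is the stationary-Poisson signature.  Undefined (NaN)
    with fewer than two intervals.
    """
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        return float("nan")
    return float(intervals.std() / intervals.mean())


def isi_cv2(intervals: np.ndarray) -> float:
    """Local coefficient of variation: mean over consecutive interval pairs
    of 2|ISI_{l+1} - ISI_l| / (ISI_{l+1} + ISI_l).

    Bounded in [0, 2]; 0 for perfectly periodic trains and 1 for
    exponentially distributed intervals (the pair ratio is then uniform),
    which makes near-unity CV2 a signature of Poisson-like spiking that is
    robust to slow rate modulation.  Undefined (NaN) with fewer than two
    intervals.
    """
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        return float("nan")
    a, b = intervals[:-1], intervals[1:]
    return float(np.mean(2.0 * np.abs(b - a) / (b + a)))


def rates_from_raster(raster: SpikeRaster) -> tuple[np.ndarray, pd.DataFrame]:
    """Population and per-neuron rates from a spike raster.

    Returns ``(pop_rates, neuron_rates)`` where ``pop_rates`` is the (T, D)
    array of per-step population rates (fraction of units whose spike has
    tuning d; rows sum to 1 in the hard-WTA regime) and ``neuron_rates`` a
    DataFrame with one row per (unit, tuning) pair that ever spiked:
    columns ``unit``, ``tuning``, ``n_spikes``, ``rate`` (= count / T).
    """
    T, D = raster.T, raster.D
    pop = np.zeros((T, D))
    np.add.at(pop, (raster.t, raster.tuning), 1.0)
    pop /= raster.N
    df = (
        pd.DataFrame({"unit": raster.unit, "tuning": raster.tuning})
        .groupby(["unit", "tuning"], as_index=False)
        .size()
        .rename(columns={"size": "n_spikes"})
    )
    df["rate"] = df["n_spikes"] / T
    return pop, df


def spike_train_stats(raster: SpikeRaster, min_isis: int = MIN_ISIS) -> pd.DataFrame:
    """Per-neuron ISI statistics for every (unit, tuning) pair in a raster.

    Columns: unit, tuning, rate, n_isis, cv, cv2, undersampled.  Neurons
    with fewer than ``min_isis`` intervals carry NaN statistics and the
    ``undersampled`` flag; exclude them from population summaries.
    """
    order = np.lexsort((raster.t, raster.tuning, raster.unit))
    u, d, t = raster.unit[order], raster.tuning[order], raster.t[order]
    keys = u.astype(np.int64) * raster.D + d
    starts = np.flatnonzero(np.r_[True, np.diff(keys) != 0])
    bounds = np.r_[starts, keys.size]
    rows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        iv = np.diff(t[a:b])
        n_iv = iv.size
        under = n_iv < min_isis
        rows.append(
            {
                "unit": int(u[a]),
                "tuning": int(d[a]),
                "rate": (b - a) / raster.T,
                "n_isis": n_iv,
                "cv": float("nan") if under else isi_cv(iv),
                "cv2": float("nan") if under else isi_cv2(iv),
                "undersampled": under,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# time-series and population measures
# ---------------------------------------------------------------------------

def autocovariance(signal: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocovariance c(0..max_lag) after mean subtraction,
    c(tau) = (1/T) sum_t (x_t - xbar)(x_{t+tau} - xbar)."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    T = x.size
    if T <= max_lag:
        raise ValueError("series shorter than max_lag")
    x = x - x.mean()
    return np.array([np.dot(x[: T - l], x[l:]) / T for l in range(max_lag + 1)])


@dataclass(frozen=True)
class ActivePopulations:
    """Active-population summary over an analysis window."""

    count: int
    active: np.ndarray
    mean_rates: np.ndarray
    info_bits: float
    uniform: bool  # no population cleared the threshold


def active_populations(
    rate_traj: np.ndarray,
    window: tuple[int, int] | None = None,
    threshold_factor: float = 1.5,
) -> ActivePopulations:
    """Count populations whose window-averaged rate exceeds threshold/D.

    A population is "active" when its mean rate over the window exceeds
    ``threshold_factor / D`` (default 1.5/D, separating elevated from
    quiescent populations while excluding the uniform state, whose rates
    are exactly 1/D).  The information content of the state is log2(count)
    bits; a count of zero is reported as the ``uniform`` flag.
    """
    traj = np.atleast_2d(np.asarray(rate_traj, dtype=float))
    if window is not None:
        a, b = window
        if not (0 <= a < b <= traj.shape[0]):
            raise ValueError("window outside trajectory")
        traj = traj[a:b]
    if traj.shape[0] == 0:
        raise ValueError("empty analysis window")
    D = traj.shape[1]
    m = traj.mean(axis=0)
    active = np.flatnonzero(m > threshold_factor / D)
    count = active.size
    return ActivePopulations(
        count=count,
        active=active,
        mean_rates=m,
        info_bits=math.log2(count) if count >= 1 else float("nan"),
        uniform=count == 0,
    )


@dataclass(frozen=True)
class RingGeometry:
    """D populations evenly spaced on a ring: theta_d = -pi + 2*pi*d/D."""

    D: int

    @property
    def positions(self) -> np.ndarray:
        return -np.pi + 2.0 * np.pi * np.arange(self.D) / self.D


def circular_mean(r: np.ndarray, geom: RingGeometry, min_resultant: float = 1e-9) -> float:
    """Argument of sum_d r_d exp(i theta_d); NaN when the resultant vanishes
    (e.g. the uniform distribution)."""
    r = np.asarray(r, dtype=float)
    z = np.sum(r * np.exp(1j * geom.positions))
    if np.abs(z) < min_resultant:
        return float("nan")
    return float(np.angle(z))


def sequence_speed(
    rate_traj: np.ndarray,
    geom: RingGeometry,
    window: tuple[int, int] | None = None,
) -> float:
    """Ring propagation speed in populations per timestep.

    Computes the circular mean of each rate vector, unwraps the phase and
    fits a least-squares line over the window; the slope is converted by
    D / (2 pi), positive for clockwise (d -> d+1) motion.  Fails if more
    than half the window has a degenerate circular mean.
    """
    traj = np.asarray(rate_traj, dtype=float)
    if window is not None:
        traj = traj[window[0] : window[1]]
    angles = np.array([circular_mean(r, geom) for r in traj])
    ok = np.isfinite(angles)
    if ok.sum() <= max(1, 0.5 * angles.size):
        raise ValueError("circular mean degenerate over most of the window")
    t = np.flatnonzero(ok)
    unwrapped = np.unwrap(angles[ok])
    slope = np.polyfit(t, unwrapped, 1)[0]
    return float(slope * geom.D / (2.0 * np.pi))


# ---------------------------------------------------------------------------
# perturbation analysis and chaos detection
# ---------------------------------------------------------------------------

def perturb_swap(
    state: np.ndarray, unit: int, rng: np.random.Generator
) -> np.ndarray:
    """Swap the most and least active neuron within one unit.

    At g = inf this moves the unit's spike to its least-active tuning (a
    "spike swap"); at finite g it exchanges two activity levels.  Ties for
    the extremes are resolved by a seeded uniform choice.  Row sums are
    preserved; all other units are untouched.
    """
    y = np.array(state, dtype=float, copy=True)
    row = y[unit]
    hi_cands = np.flatnonzero(row == row.max())
    hi = hi_cands[0] if hi_cands.size == 1 else int(rng.choice(hi_cands))
    lo_cands = np.flatnonzero(row == row.min())
    lo_cands = lo_cands[lo_cands != hi]
    if lo_cands.size == 0:  # constant row: nothing to swap
        return y
    lo = lo_cands[0] if lo_cands.size == 1 else int(rng.choice(lo_cands))
    row[hi], row[lo] = row[lo], row[hi]
    return y


def state_distance(a: np.ndarray, b: np.ndarray, kind: str = "euclidean") -> float:
    """Euclidean or RMS distance between two full activation states."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("state shapes differ")
    d = float(np.sqrt(np.sum((a - b) ** 2)))
    if kind == "euclidean":
        return d
    if kind == "rms":
        return d / math.sqrt(a.size)
    raise ValueError(f"unknown distance kind {kind!r}")


@dataclass(frozen=True)
class ChaosVerdict:
    """Outcome of the perturbation-growth test."""

    chaotic: bool
    distances: np.ndarray  # d(t) for t = 0 (perturbation) .. t_post
    perturbation_time: int
    perturbed_unit: int


def _advance(y, W, ext, g, tie_rng):
    if math.isinf(g):
        x = compute_inputs(y, W, ext)
        winners = _hard_winners(x, tie_rng)
        out = np.zeros_like(y)
        out[np.arange(y.shape[0]), winners] = 1.0
        return out
    return softmax_activation(compute_inputs(y, W, ext), g)


def chaos_test(
    config: ModelConfig,
    spec: WeightSpec,
    schedule: InputSchedule | None = None,
    t_pre: int = 10,
    t_post: int = 20,
    seed: int | None = None,
    W: WeightTensor | None = None,
    criterion: str = "endpoint",
) -> ChaosVerdict:
    """Perturbation-growth chaos test on the full network.

    Procedure: (1) run the network for ``t_pre`` steps, (2) clone the state,
    (3) swap the most and least active neuron of one seeded unit in the
    clone, (4) run both copies forward ``t_post`` steps with identical
    external-input draws, (5) record the Euclidean distance between the two
    complete states at every step, (6) label the network chaotic if the
    distance grew following the perturbation.

    criterion : {"endpoint", "slope"}
        "endpoint" compares the final distance with the distance at the
        first post-perturbation step; "slope" uses the sign of the fitted
        slope of log distance (distances clipped away from zero).
    """
    if t_post < 2:
        raise ValueError("t_post must be >= 2")
    if seed is None:
        seed = config.seed
    if schedule is None:
        schedule = InputSchedule.empty(config.D)
    if W is None:
        W = sample_weights(
            spec,
            config.N,
            seed,
            "dense" if config.N * config.D <= 20_000 else "blockwise",
        )
    cfg = replace(config, seed=seed)
    tie_a = stream(seed, "ties", 0)
    tie_b = stream(seed, "ties", 1)
    ext_rng = stream(seed, "external")
    has_input = bool(schedule.epochs)

    y = initial_state(cfg)
    for t in range(t_pre):
        ext = draw_external(schedule, t, cfg.N, ext_rng) if has_input else None
        y = _advance(y, W, ext, cfg.g, tie_a)

    unit = int(stream(seed, "perturb-unit").integers(cfg.N))
    y_ref = y
    y_pert = perturb_swap(y, unit, stream(seed, "perturb-ties"))
    dists = [state_distance(y_ref, y_pert)]
    for t in range(t_pre, t_pre + t_post):
        ext = draw_external(schedule, t, cfg.N, ext_rng) if has_input else None
        y_ref = _advance(y_ref, W, ext, cfg.g, tie_a)
        y_pert = _advance(y_pert, W, ext, cfg.g, tie_b)
        dists.append(state_distance(y_ref, y_pert))
    dists = np.array(dists)

    if dists[0] == 0.0:  # identical clones can never diverge
        chaotic = False
    elif criterion == "endpoint":
        chaotic = dists[-1] > dists[1]
    elif criterion == "slope":
        logd = np.log(np.maximum(dists[1:], 1e-300))
        chaotic = np.polyfit(np.arange(logd.size), logd, 1)[0] > 0
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return ChaosVerdict(
        chaotic=bool(chaotic),
        distances=dists,
        perturbation_time=t_pre,
        perturbed_unit=unit,
    )


def _majority_chaotic(config, spec, g, seeds, weights, **kw) -> bool:
    votes = 0
    for s, W in zip(seeds, weights):
        cfg = replace(config, g=g, seed=s)
        if chaos_test(cfg, spec, seed=s, W=W, **kw).chaotic:
            votes += 1
    return votes * 2 > len(seeds)


def critical_gain(
    config: ModelConfig,
    spec: WeightSpec,
    g_lo: float,
    g_hi: float,
    tol: float = 0.05,
    votes: int = 5,
    seed: int | None = None,
    **chaos_kw,
) -> float:
    """Bisection estimate of the gain at which perturbations start to grow.

    Requires a valid bracket: the majority chaos verdict over ``votes``
    seeded network realizations must be False at ``g_lo`` and True at
    ``g_hi``.  Each realization's quenched weights are sampled once and
    reused across gains.  Returns the bracket midpoint once its width is
    below ``tol``.
    """
    if seed is None:
        seed = config.seed
    seeds = spawn_seeds(seed, "critical-gain", votes)
    mode = "dense" if config.N * config.D <= 20_000 else "blockwise"
    weights = [sample_weights(spec, config.N, s, mode) for s in seeds]
    lo_chaotic = _majority_chaotic(config, spec, g_lo, seeds, weights, **chaos_kw)
    hi_chaotic = _majority_chaotic(config, spec, g_hi, seeds, weights, **chaos_kw)
    if lo_chaotic or not hi_chaotic:
        raise ValueError(
            f"invalid bracket: majority verdicts must differ "
            f"(g_lo={g_lo}: {lo_chaotic}, g_hi={g_hi}: {hi_chaotic})"
        )
    lo, hi = float(g_lo), float(g_hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _majority_chaotic(config, spec, mid, seeds, weights, **chaos_kw):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
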