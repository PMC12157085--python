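"""Weight-statistics specifications and connectivity presets.

A network of winner-take-all units is parameterized, at the level of its
connectivity statistics, by two D x D matrices: the per-block means
mu_J(d, d') and variances sigma_J^2(d, d') of the synaptic weights from
neurons with tuning d' onto neurons with tuning d.  The same two matrices
drive both the microscopic simulator and the mean-field rate dynamics.

Conventions
-----------
* Preset scalars written ``(sigma_J)x`` in the literature are standard
  deviations.  They are accepted as standard deviations here and stored
  squared (as variances).  This is deliberate and worth repeating:
  **presets take std-dev scalars; WeightSpec stores variances.**
* "Clockwise neighbor" of population d is d+1 mod D, with populations
  placed on a ring at angles theta_d = -pi + 2*pi*d/D.
* The sequence preset's asymmetric term *adds* shift^2 to the baseline
  off-diagonal variance (variances of independent components add), so the
  preset is continuous in the shift at 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rng import stream

__all__ = [
    "WeightSpec",
    "preset_unstructured",
    "preset_multistable",
    "preset_sequence",
    "preset_heterogeneous",
    "PRESETS",
    "build_preset",
]


@dataclass(frozen=True)
class WeightSpec:
    """Per-block weight statistics: mean and variance matrices.

    Entry (d, d') of ``mean_matrix`` is mu_J(d, d'): the mean weight from a
    neuron with tuning d' onto a neuron with tuning d, before the D/N
    scaling applied at sampling time.  ``var_matrix`` holds sigma_J^2(d, d')
    with the same convention.
    """

    mean_matrix: np.ndarray
    var_matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_matrix, dtype=float)
        v = np.asarray(self.var_matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mean_matrix must be square")
        if v.shape != m.shape:
            raise ValueError("mean_matrix and var_matrix shapes differ")
        if m.shape[0] < 1:
            raise ValueError("need at least one population")
        if np.any(v < 0):
            raise ValueError("variance entries must be nonnegative")
        if not (np.all(np.isfinite(m)) and np.all(np.isfinite(v))):
            raise ValueError("weight statistics must be finite")
        object.__setattr__(self, "mean_matrix", m)
        object.__setattr__(self, "var_matrix", v)

    @property
    def D(self) -> int:
        return self.mean_matrix.shape[0]

    def __eq__(self, other) -> bool:  # dataclass eq fails on arrays
        if not isinstance(other, WeightSpec):
            return NotImplemented
        return np.array_equal(self.mean_matrix, other.mean_matrix) and np.array_equal(
            self.var_matrix, other.var_matrix
        )

    def __hash__(self):
        return hash((self.mean_matrix.tobytes(), self.var_matrix.tobytes()))


def preset_unstructured(D: int) -> WeightSpec:
    """Homogeneous random network: mu_J = 0 and sigma_J^2 = 1 everywhere.

    This is the baseline regime in which the uniform rate distribution is
    globally attracting in one step and spiking at infinite gain is
    Poisson-like.
    """
    if D < 2:
        raise ValueError("D must be >= 2")
    return WeightSpec(np.zeros((D, D)), np.ones((D, D)))


def preset_multistable(
    D: int, mode: str, diag: float, offdiag: float | None = None
) -> WeightSpec:
    """Multistable network via self-coupling within each co-tuned population.

    Parameters
    ----------
    mode : {"mean", "variance"}
        ``"mean"``: raise the diagonal of mu_J to ``diag`` (off-diagonal
        ``offdiag``, default 0), leaving unit weight variances; states are
        stabilized by positive mean feedback (mean-driven regime).
        ``"variance"``: raise the diagonal of sigma_J to ``diag`` (a standard
        deviation; stored squared), off-diagonal std ``offdiag`` (default 0),
        zero means; states are stabilized purely by input fluctuations
        (fluctuation-driven regime, preserving irregular spiking).
    """
    if D < 2:
        raise ValueError("D must be >= 2")
    if mode == "mean":
        off = 0.0 if offdiag is None else float(offdiag)
        mean = np.full((D, D), off)
        np.fill_diagonal(mean, float(diag))
        return WeightSpec(mean, np.ones((D, D)))
    if mode == "variance":
        if diag < 0 or (offdiag is not None and offdiag < 0):
            raise ValueError("standard deviations must be nonnegative")
        off = 0.0 if offdiag is None else float(offdiag)
        var = np.full((D, D), off**2)
        np.fill_diagonal(var, float(diag) ** 2)
        return WeightSpec(np.zeros((D, D)), var)
    raise ValueError(f"unknown mode {mode!r}; expected 'mean' or 'variance'")


def preset_sequence(
    D: int, mode: str, diag: float, offdiag: float | None = None, shift: float = 0.0
) -> WeightSpec:
    """Sequence-generating ring network.

    Starts from :func:`preset_multistable` and adds a unidirectional term
    from each population d to its clockwise neighbor d+1 mod D: ``shift`` is
    added to the mean (mode "mean") or ``shift**2`` to the variance (mode
    "variance") of entry (d+1 mod D, d).  With shift = 0 this reduces
    exactly to the multistable preset.
    """
    base = preset_multistable(D, mode, diag, offdiag)
    if shift == 0.0:
        return base
    nxt = (np.arange(D) + 1) % D
    if mode == "mean":
        mean = base.mean_matrix.copy()
        mean[nxt, np.arange(D)] += float(shift)
        return WeightSpec(mean, base.var_matrix)
    var = base.var_matrix.copy()
    var[nxt, np.arange(D)] += float(shift) ** 2
    return WeightSpec(base.mean_matrix, var)


def preset_heterogeneous(D: int, K_sigma: int, var_r: float, seed: int) -> WeightSpec:
    """Sparse random variance couplings on top of a diagonal variance matrix.

    mu_J = 0 everywhere; sigma_J^2 has unit diagonal and, in each row,
    ``K_sigma`` distinct off-diagonal positions (chosen uniformly without
    replacement, seeded) set to ``var_r``.  Note ``var_r`` is a *variance*,
    matching the literature's (sigma_J^2)_r notation.  For 0 << K_sigma << D
    this regime produces slow, heterogeneous firing-rate dynamics.
    """
    if D < 2:
        raise ValueError("D must be >= 2")
    if not 0 <= K_sigma <= D - 1:
        raise ValueError("K_sigma must lie in [0, D-1]")
    if var_r < 0:
        raise ValueError("var_r must be nonnegative")
    rng = stream(seed, "heterogeneous-pattern")
    var = np.eye(D)
    for d in range(D):
        offs = np.delete(np.arange(D), d)
        cols = rng.choice(offs, size=K_sigma, replace=False)
        var[d, cols] = var_r
    return WeightSpec(np.zeros((D, D)), var)


PRESETS = {
    "unstructured": preset_unstructured,
    "multistable": preset_multistable,
    "sequence": preset_sequence,
    "heterogeneous": preset_heterogeneous,
}


def build_preset(name: str, **params) -> WeightSpec:
    """Construct a preset by name (used by the config loader and CLI)."""
    try:
        fn = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return fn(**params)
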