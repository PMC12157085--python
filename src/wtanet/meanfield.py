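"""Mean-field firing-rate dynamics on the probability simplex.

In the hard-WTA limit the population firing rates r_t (a categorical
distribution over the D tunings) evolve by an argmax-of-Gaussians map:

    r_d(t) = P[ X_d > X_{d'} for all d' != d ],   X_d ~ Normal(mu_d, sigma_d^2)

where the input moments are linear in the previous rates,

    mu_d      = D * sum_{d'} mu_J(d,d')      r_{d'}(t-1) + u_d(t)
    sigma_d^2 = D * sum_{d'} sigma_J^2(d,d') r_{d'}(t-1) + v_d(t).

In the N -> infinity limit the map is deterministic.  For finite N the spike
counts n_t ~ Multinomial(r_t, N) are sampled each step and the moments are
evaluated at the empirical rates n/N, making the dynamics stochastic.

The argmax-of-Gaussians integral

    r_d = int Normal(x; mu_d, sigma_d^2) prod_{d' != d} Phi(x; mu_d', sigma_d'^2) dx

is evaluated by Gauss-Hermite quadrature centered on the d-th Gaussian
(substitute x = mu_d + sqrt(2) sigma_d z), with the product of normal CDFs
accumulated as a sum of log-CDFs for numerical range, then the result is
renormalized to sum exactly to 1.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable

import numpy as np
from scipy.linalg import null_space
from scipy.special import log_ndtr, logsumexp

from .connectivity import WeightSpec
from .core import InputSchedule
from .rng import stream

__all__ = [
    "argmax_gaussian",
    "moments_infinite",
    "moments_finite",
    "sample_counts",
    "step_meanfield",
    "simulate_meanfield",
    "iterate_to_fixed_point",
    "jacobian_at",
    "StabilityReport",
    "find_destabilization_D",
    "track_destabilized_attractor",
]

DEFAULT_NODES = 201
#: Relative floor applied to input variances so the integrand stays defined
#: when a population's input variance vanishes.
VAR_FLOOR = 1e-12


@lru_cache(maxsize=8)
def _gh(nodes: int) -> tuple[np.ndarray, np.ndarray]:
    z, w = np.polynomial.hermite.hermgauss(nodes)
    return z, np.log(w)


def _validate_simplex(r: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size < 1:
        raise ValueError("rate vector must be 1-D")
    if np.any(r < -tol) or abs(r.sum() - 1.0) > tol:
        raise ValueError("rate vector must lie on the probability simplex")
    return np.clip(r, 0.0, None)


def argmax_gaussian(
    mu: np.ndarray, sigma2: np.ndarray, nodes: int = DEFAULT_NODES
) -> np.ndarray:
    """Distribution of the argmax of D independent Gaussians.

    Returns the probability vector r with r_d the probability that a sample
    from Normal(mu_d, sigma2_d) exceeds samples from all the others.
    Degenerate case (all variances zero): argmax of the means, with ties
    split uniformly.
    """
    mu = np.asarray(mu, dtype=float)
    s2 = np.asarray(sigma2, dtype=float)
    if mu.shape != s2.shape or mu.ndim != 1:
        raise ValueError("mu and sigma2 must be 1-D with equal length")
    if np.any(s2 < 0):
        raise ValueError("variances must be nonnegative")
    D = mu.size
    if D == 1:
        return np.ones(1)
    if np.all(s2 == 0):
        win = np.isclose(mu, mu.max())
        return win / win.sum()
    floor = VAR_FLOOR * max(1.0, float(s2.max()))
    s2 = np.maximum(s2, floor)
    sd = np.sqrt(s2)
    z, logw = _gh(nodes)
    X = mu[:, None] + np.sqrt(2.0) * sd[:, None] * z[None, :]          # (D, M)
    Z = (X[:, None, :] - mu[None, :, None]) / sd[None, :, None]        # (D, D', M)
    A = log_ndtr(Z)
    S = A.sum(axis=1) - np.einsum("ddm->dm", A)                        # exclude d'=d
    logr = logsumexp(S + logw[None, :], axis=1) - 0.5 * np.log(np.pi)
    r = np.exp(logr)
    total = r.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError("quadrature failed to produce a distribution")
    return r / total


def moments_infinite(
    r_prev: np.ndarray,
    spec: WeightSpec,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Large-N input moments: mu = D mu_J r + u, sigma^2 = D sigma_J^2 r + v."""
    r_prev = np.asarray(r_prev, dtype=float)
    D = spec.D
    if r_prev.shape != (D,):
        raise ValueError(f"r_prev must have shape ({D},)")
    mu = D * (spec.mean_matrix @ r_prev)
    s2 = D * (spec.var_matrix @ r_prev)
    if u is not None:
        mu = mu + np.asarray(u, dtype=float)
    if v is not None:
        v = np.asarray(v, dtype=float)
        if np.any(v < 0):
            raise ValueError("input variances must be nonnegative")
        s2 = s2 + v
    return mu, s2


def moments_finite(
    n_prev: np.ndarray,
    N: int,
    spec: WeightSpec,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Finite-N input moments, evaluated at the empirical rates n/N."""
    n_prev = np.asarray(n_prev)
    if n_prev.sum() != N:
        raise ValueError("spike counts must sum to N")
    return moments_infinite(n_prev / float(N), spec, u, v)


def sample_counts(r: np.ndarray, N: int, rng: np.random.Generator) -> np.ndarray:
    """One multinomial draw of per-population spike counts (sums to N)."""
    r = _validate_simplex(r)
    return rng.multinomial(N, r / r.sum())


def step_meanfield(
    r_prev: np.ndarray,
    spec: WeightSpec,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
    N: int | None = None,
    rng: np.random.Generator | None = None,
    nodes: int = DEFAULT_NODES,
) -> np.ndarray:
    """One step of the rate dynamics.

    ``N=None`` gives the deterministic infinite-size map.  With finite
    ``N`` (requires ``rng``) the step returns the *realized* population
    rates n/N, where n ~ Multinomial(P, N) and P is the argmax-of-Gaussians
    probability computed from the previous realized rates: spike counts are
    what a finite network actually emits, so the observable rates fluctuate
    multinomially around P even when P itself is pinned by symmetry (e.g.
    the unstructured network, whose input variances are independent of the
    count split by activity conservation).
    """
    mu, s2 = moments_infinite(r_prev, spec, u, v)
    P = argmax_gaussian(mu, s2, nodes=nodes)
    if N is None:
        return P
    if rng is None:
        raise ValueError("finite-N dynamics require an rng")
    return sample_counts(P, N, rng) / float(N)


def simulate_meanfield(
    spec: WeightSpec,
    T: int,
    schedule: InputSchedule | None = None,
    N: int | None = None,
    r0: np.ndarray | None = None,
    seed: int = 0,
    nodes: int = DEFAULT_NODES,
) -> np.ndarray:
    """Rate trajectory of shape (T+1, D); row 0 is the initial condition.

    ``r0`` defaults to the uniform distribution.  Finite-N runs draw their
    multinomial samples from the named "meanfield" stream of ``seed``.
    """
    D = spec.D
    r = np.full(D, 1.0 / D) if r0 is None else _validate_simplex(np.asarray(r0, float))
    if r.size != D:
        raise ValueError("r0 dimension does not match spec")
    if schedule is None:
        schedule = InputSchedule.empty(D)
    rng = stream(seed, "meanfield") if N is not None else None
    traj = np.empty((T + 1, D))
    traj[0] = r
    for t in range(T):
        u, v = schedule.moments_at(t)
        r = step_meanfield(r, spec, u, v, N=N, rng=rng, nodes=nodes)
        traj[t + 1] = r
    return traj


def iterate_to_fixed_point(
    r0: np.ndarray,
    spec: WeightSpec,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
    tol: float = 1e-9,
    max_steps: int = 1000,
    nodes: int = DEFAULT_NODES,
) -> tuple[np.ndarray, bool, int]:
    """Iterate the deterministic map until max|r_t - r_{t-1}| < tol.

    Returns (r, converged, steps_taken).
    """
    r = _validate_simplex(np.asarray(r0, float))
    for k in range(max_steps):
        r_next = step_meanfield(r, spec, u, v, nodes=nodes)
        if np.max(np.abs(r_next - r)) < tol:
            return r_next, True, k + 1
        r = r_next
    return r, False, max_steps


@dataclass
class StabilityReport:
    """Linearization of the deterministic map at a rate vector.

    ``lambda_max`` is the spectral radius of the Jacobian restricted to the
    simplex tangent space (perturbations summing to zero) - the instability
    criterion for the discrete-time map is lambda_max > 1.  The unrestricted
    D x D Jacobian and both spectra are reported alongside.
    """

    jacobian: np.ndarray
    tangent_jacobian: np.ndarray
    lambda_max: float
    spectrum: np.ndarray
    full_spectrum: np.ndarray
    epsilon: float

    def to_jsonable(self) -> dict:
        return {
            "D": int(self.jacobian.shape[0]),
            "epsilon": self.epsilon,
            "lambda_max": self.lambda_max,
            "spectrum": [[z.real, z.imag] for z in np.asarray(self.spectrum, complex)],
            "full_spectrum": [
                [z.real, z.imag] for z in np.asarray(self.full_spectrum, complex)
            ],
            "jacobian": self.jacobian.tolist(),
        }


def jacobian_at(
    r: np.ndarray,
    spec: WeightSpec,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
    epsilon: float = 1e-6,
    nodes: int = DEFAULT_NODES,
) -> StabilityReport:
    """Central-finite-difference Jacobian of the infinite-N map at ``r``.

    Tangent-space restriction uses an orthonormal basis of the zero-sum
    subspace.  Steps too small to move the map (differences all underflow)
    are escalated with a warning; the common published choice epsilon=1e-12
    is available but numerically fragile in double precision, hence the
    1e-6 default.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    r = np.asarray(r, dtype=float)
    D = r.size
    B = null_space(np.ones((1, D)))  # D x (D-1), orthonormal

    def fd(eps: float) -> np.ndarray:
        cols = []
        for k in range(D - 1):
            fp = step_meanfield(r + eps * B[:, k], spec, u, v, nodes=nodes)
            fm = step_meanfield(r - eps * B[:, k], spec, u, v, nodes=nodes)
            cols.append((fp - fm) / (2.0 * eps))
        return np.column_stack(cols)  # D x (D-1)

    eps = float(epsilon)
    M = fd(eps)
    while not np.any(M) and eps < 1e-4:
        warnings.warn(
            f"finite-difference step {eps:g} produced no change; escalating",
            RuntimeWarning,
            stacklevel=2,
        )
        eps *= 100.0
        M = fd(eps)
    Jt = B.T @ M
    spec_t = np.linalg.eigvals(Jt)
    lam = float(np.max(np.abs(spec_t))) if spec_t.size else 0.0

    # unrestricted coordinate Jacobian (the map extends linearly off the
    # simplex through the moment functionals)
    cols = []
    for d in range(D):
        e = np.zeros(D)
        e[d] = eps
        fp = step_meanfield(r + e, spec, u, v, nodes=nodes)
        fm = step_meanfield(r - e, spec, u, v, nodes=nodes)
        cols.append((fp - fm) / (2.0 * eps))
    Jfull = np.column_stack(cols)
    return StabilityReport(
        jacobian=Jfull,
        tangent_jacobian=Jt,
        lambda_max=lam,
        spectrum=spec_t,
        full_spectrum=np.linalg.eigvals(Jfull),
        epsilon=eps,
    )


def find_destabilization_D(
    spec_family: Callable[[int], WeightSpec],
    D_range: Iterable[int],
    epsilon: float = 1e-6,
    nodes: int = DEFAULT_NODES,
) -> int | None:
    """Smallest D in ``D_range`` at which the uniform state is unstable.

    Evaluates lambda_max of the tangent-restricted Jacobian at r = 1/D for
    each D and returns the first with lambda_max > 1, or None.
    """
    D_range = list(D_range)
    if not D_range:
        raise ValueError("empty D range")
    for D in D_range:
        spec = spec_family(D)
        rep = jacobian_at(np.full(D, 1.0 / D), spec, epsilon=epsilon, nodes=nodes)
        if rep.lambda_max > 1.0:
            return D
    return None


def track_destabilized_attractor(
    spec_family: Callable[[int], WeightSpec],
    D_max: int,
    seed: int = 0,
    D_range: Iterable[int] | None = None,
    perturbation: float = 1e-3,
    tol: float = 1e-12,
    max_steps: int = 500,
    nodes: int = DEFAULT_NODES,
) -> dict[int, np.ndarray]:
    """Follow the attractor born when the uniform state destabilizes.

    At the destabilization D* (smallest D with lambda_max > 1) the dynamics
    are started from the uniform state plus a small seeded zero-sum
    perturbation and iterated to a steady state.  The attractor is then
    continued to larger D by appending quiescent populations (a small equal
    share of rate mass) and re-converging at each D.  Returns the steady
    rate vector for every D from D* to D_max.

    This reproduces the branch of states actually reached when slowly
    growing the network out of the uniform regime; at larger D additional
    attractors with different support sizes coexist with this branch.
    """
    if D_range is None:
        D_range = range(2, D_max + 1)
    D_star = find_destabilization_D(spec_family, D_range, nodes=nodes)
    if D_star is None:
        raise ValueError("uniform state never destabilizes over the D range")
    rng = stream(seed, "attractor-perturbation")
    out: dict[int, np.ndarray] = {}
    delta = rng.standard_normal(D_star)
    delta -= delta.mean()
    r = np.full(D_star, 1.0 / D_star) + perturbation * delta / D_star
    r = np.clip(r, 0, None)
    r /= r.sum()
    r, _, _ = iterate_to_fixed_point(
        r, spec_family(D_star), tol=tol, max_steps=max_steps, nodes=nodes
    )
    out[D_star] = r
    for D in range(D_star + 1, D_max + 1):
        r = np.concatenate([out[D - 1], [perturbation / D]])
        r /= r.sum()
        r, _, _ = iterate_to_fixed_point(
            r, spec_family(D), tol=tol, max_steps=max_steps, nodes=nodes
        )
        out[D] = r
    return out
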