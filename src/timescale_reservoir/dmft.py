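"""Dynamic mean-field theory for networks with heterogeneous self-couplings.

In the large-N limit the network reduces to uncoupled single-unit equations

    dx_a/dt = -x_a + s_a tanh(x_a) + eta(t),

one per self-coupling value s_a, driven by a shared Gaussian mean field
eta(t) with autocorrelation g^2 C(tau), where C is determined
self-consistently:

    C(tau) = sum_a n_a < phi[x_a(t)] phi[x_a(t+tau)] >.

The iterative solver alternates between (i) sampling stationary Gaussian
paths eta with the current C via its Fourier spectrum and (ii) integrating
the single-unit equations against those paths and re-estimating C, damping
with the cumulative mean across iterations.  The same module computes the
static fixed-point self-consistency, the stability condition

    g^2 sum_a n_a < 1/q_a > <= 1,   q_a = [s_a - cosh^2(x_a)]^2,

and phase boundaries in parameter space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .rate import SelfCouplingSpec, ValidationError, sample_self_couplings
from .stats import hwhm_from_curve

__all__ = [
    "DMFTSolution",
    "FixedPointStats",
    "noise_path_from_autocorr",
    "solve_unit_ode",
    "iterate_dmft",
    "static_selfconsistent",
    "stability_lhs",
    "classify_phase",
    "phase_boundary",
    "critical_gain",
]


@dataclass
class DMFTSolution:
    """Converged mean-field autocorrelation and derived quantities.

    ``lags``/``C`` give the population autocorrelation on [0, T/2);
    ``per_s`` maps each evaluated self-coupling to (autocorrelation, HWHM
    timescale).  ``D`` is the integral of C over positive lags (the noise
    strength of the mean field is then g^2 D), ``tau1`` its HWHM.
    """

    lags: np.ndarray
    C: np.ndarray
    per_s: dict
    D: float
    tau1: float
    g: float
    converged: bool
    iterations: int

    @property
    def noise_strength(self) -> float:
        """Integrated autocorrelation of the mean field itself, g^2 * D."""
        return self.g**2 * self.D


def _circular_extension(C_onesided: np.ndarray, M: int) -> np.ndarray:
    """Symmetric periodic extension of a one-sided autocorrelation."""
    C = np.zeros(M)
    n = min(C_onesided.size, M // 2 + 1)
    C[:n] = C_onesided[:n]
    C[M - n + 1:] = C_onesided[1:n][::-1]
    return C


def noise_path_from_autocorr(
    C: np.ndarray,
    g: float,
    duration: float,
    dt: float,
    seed: int | np.random.Generator,
    n_paths: int = 1,
) -> np.ndarray:
    """Sample stationary Gaussian paths with autocorrelation g^2 C(tau).

    ``C`` is the one-sided autocorrelation sampled on the same dt grid
    (C[0] = variance).  Paths are generated spectrally: the periodic
    symmetric extension of C is Fourier transformed, negative spectral
    values are clipped to zero (iterates of the DMFT loop need not be valid
    autocorrelations), and independent Gaussian Fourier coefficients with
    that spectrum are transformed back.  Returns (n_paths, M) with
    M = duration/dt.
    """
    C = np.asarray(C, float)
    if C.ndim != 1 or C.size < 2:
        raise ValidationError("C must be a one-sided 1-D autocorrelation")
    if not np.all(np.isfinite(C)):
        raise ValidationError("C must be finite")
    if C[0] <= 0 or np.max(np.abs(C)) > C[0] * (1 + 1e-9):
        raise ValidationError("C must peak at lag 0 with C[0] > 0")
    M = int(round(duration / dt))
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    C_circ = _circular_extension(C, M)
    S = np.clip(np.fft.rfft(C_circ).real, 0.0, None)
    amp = np.sqrt(S * M)
    nf = S.size
    z = (
        rng.standard_normal((n_paths, nf))
        + 1j * rng.standard_normal((n_paths, nf))
    ) / math.sqrt(2.0)
    z[:, 0] = rng.standard_normal(n_paths)
    if M % 2 == 0:
        z[:, -1] = rng.standard_normal(n_paths)
    eta = np.fft.irfft(amp * z, n=M, axis=1)
    return g * eta


def solve_unit_ode(
    s: float | np.ndarray,
    noise: np.ndarray,
    dt: float,
    x0: float = 0.0,
    n_passes: int = 3,
) -> np.ndarray:
    """Euler-integrate dx/dt = -x + s tanh x + eta against given paths.

    ``noise`` has shape (n_units, M) (or (M,) for a single unit) and is
    treated as periodic: the integration sweeps the path ``n_passes`` times
    and records the last sweep, so the returned series is stationary.
    """
    eta = np.atleast_2d(np.asarray(noise, float))
    n_units, M = eta.shape
    s_arr = np.broadcast_to(np.asarray(s, float), (n_units,))
    x = np.full(n_units, float(x0))
    out = np.empty((n_units, M))
    for rep in range(n_passes):
        last = rep == n_passes - 1
        for t in range(M):
            x = x + dt * (-x + s_arr * np.tanh(x) + eta[:, t])
            if last:
                out[:, t] = x
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite state in mean-field unit ODE")
    return out if np.ndim(noise) == 2 else out[0]


def _circ_autocorr(y: np.ndarray) -> np.ndarray:
    """Mean-over-rows circular autocorrelation (biased, no mean removal)."""
    M = y.shape[1]
    Y = np.fft.rfft(y, axis=1)
    ac = np.fft.irfft(np.abs(Y) ** 2, n=M, axis=1) / M
    return ac.mean(axis=0)


def iterate_dmft(
    spec: SelfCouplingSpec,
    g: float,
    duration: float = 1200.0,
    dt: float = 0.02,
    n_paths: int = 40,
    tol: float = 1e-2,
    max_iter: int = 60,
    warmup: int = 20,
    draw_schedule: Sequence[int] = (8, 16, 32, 64, 128, 256, 512),
    eval_s: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> DMFTSolution:
    """Solve the mean-field self-consistency iteratively.

    Discrete specs integrate ``n_paths`` units per self-coupling value and
    weight the per-value autocorrelations by n_alpha.  Continuous specs
    draw fresh s values each iteration, doubling the number of draws as the
    iterations progress, and average the per-draw autocorrelations with
    weight 1/n.  The running estimate of C is the cumulative mean over
    post-warmup iterations; convergence is sup-norm change of the
    normalized C below ``tol``.  ``eval_s`` requests per-self-coupling
    autocorrelations (and HWHM timescales) evaluated against the converged
    mean field.
    """
    if g <= 0:
        raise ValidationError("g must be positive")
    rng = np.random.default_rng(seed)
    M = int(round(duration / dt))
    lags_full = np.arange(M) * dt
    # initial guess: unit-variance bump of width ~5 time constants
    wrap = np.minimum(lags_full, duration - lags_full)
    C = np.exp(-0.5 * (wrap / 5.0) ** 2)

    discrete = spec.kind == "discrete"
    if discrete:
        s_vals = np.asarray(spec.values, float)
        weights = np.asarray(spec.fractions, float)

    C_sum = None
    n_avg = 0
    prev = None
    converged = False
    it = 0
    for it in range(max_iter):
        if discrete:
            units_s = np.repeat(s_vals, n_paths)
            eta = noise_path_from_autocorr(
                C[: M // 2], g, duration, dt, rng, n_paths=units_s.size
            )
            xs = solve_unit_ode(units_s, eta, dt)
            phis = np.tanh(xs)
            Cn = np.zeros(M)
            for v, w in zip(s_vals, weights):
                Cn += w * _circ_autocorr(phis[units_s == v])
        else:
            n_draw = draw_schedule[min(it, len(draw_schedule) - 1)]
            units_s = sample_self_couplings(
                spec, n_draw, int(rng.integers(2**31))
            )
            eta = noise_path_from_autocorr(
                C[: M // 2], g, duration, dt, rng, n_paths=n_draw
            )
            xs = solve_unit_ode(units_s, eta, dt)
            Cn = _circ_autocorr(np.tanh(xs))
        if it < warmup:
            C = Cn
        else:
            if C_sum is None:
                C_sum = np.zeros_like(Cn)
            C_sum += Cn
            n_avg += 1
            C = C_sum / n_avg
        cn = C / C[0] if C[0] > 0 else C
        if prev is not None and n_avg >= 20:
            if np.max(np.abs(cn - prev)) < tol:
                converged = True
                break
        prev = cn

    half = M // 2
    lags = lags_full[:half]
    C_one = C[:half].copy()
    tau1 = hwhm_from_curve(lags, C_one)
    # integrate C to its first zero crossing (tail noise is pure variance)
    zc = np.nonzero(C_one <= 0)[0]
    kmax = int(zc[0]) if zc.size else half
    D = float(np.trapezoid(C_one[:kmax], lags[:kmax]))

    per_s: dict = {}
    if eval_s is None and discrete:
        eval_s = [float(v) for v in s_vals]
    if eval_s:
        eta = noise_path_from_autocorr(
            C[:half], g, duration, dt, rng, n_paths=len(eval_s) * n_paths
        )
        units_s = np.repeat(np.asarray(eval_s, float), n_paths)
        xs = solve_unit_ode(units_s, eta, dt)
        phis = np.tanh(xs)
        # per-unit means removed so the conditional timescale is the HWHM
        # of the fluctuation autocorrelation (bistable units otherwise
        # carry a window-dependent plateau from their well occupancy)
        phis = phis - phis.mean(axis=1, keepdims=True)
        for v in eval_s:
            ca = _circ_autocorr(phis[units_s == v])[:half]
            per_s[float(v)] = (ca, hwhm_from_curve(lags, ca))

    return DMFTSolution(
        lags=lags,
        C=C_one,
        per_s=per_s,
        D=D,
        tau1=tau1,
        g=g,
        converged=converged,
        iterations=it + 1,
    )


# ---------------------------------------------------------------------------
# Static fixed points and stability
# ---------------------------------------------------------------------------

_GH_NODES = 201


def _gauss_hermite(std: float):
    """Nodes/weights for E[f(eta)], eta ~ N(0, std^2)."""
    nodes, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    return nodes * std, w / w.sum()


def _outer_root(s: float, eta: float, branch_sign: float) -> float:
    """Root of x - s tanh x = eta on the outer branch with given sign.

    For s <= 1 the equation has a unique root.  For s > 1, the outer roots
    satisfy cosh^2 x > s; ``branch_sign`` selects the positive or negative
    one where both exist.
    """
    if s <= 1.0:
        lo, hi = eta - abs(s) - 1.0, eta + abs(s) + 1.0
        return brentq(lambda x: x - s * math.tanh(x) - eta, lo, hi, xtol=1e-12)
    x_t = math.acosh(math.sqrt(s))  # fold location
    if branch_sign > 0:
        lo, hi = x_t, abs(eta) + s + 1.0
    else:
        lo, hi = -(abs(eta) + s + 1.0), -x_t
    f_lo = lo - s * math.tanh(lo) - eta
    f_hi = hi - s * math.tanh(hi) - eta
    if f_lo * f_hi > 0:
        # no root on this side: fall back to the unique global root
        lo, hi = -(abs(eta) + s + 1.0), abs(eta) + s + 1.0
    return brentq(lambda x: x - s * math.tanh(x) - eta, lo, hi, xtol=1e-12)


def _branch_roots(s: float, eta: float, branch: str) -> list[tuple[float, float]]:
    """(x, weight) pairs of fixed-point solutions for one eta sample."""
    if s <= 1.0:
        return [(_outer_root(s, eta, +1.0), 1.0)]
    if branch == "most_stable":
        # sign-aligned outer root maximizes |x| (most stable choice)
        sign = 1.0 if eta >= 0 else -1.0
        return [(_outer_root(s, eta, sign), 1.0)]
    # 'sampled': both outer roots with equal weight where both exist
    eta_fold = -(
        math.acosh(math.sqrt(s)) - s * math.tanh(math.acosh(math.sqrt(s)))
    )
    if abs(eta) < eta_fold:
        return [
            (_outer_root(s, eta, +1.0), 0.5),
            (_outer_root(s, eta, -1.0), 0.5),
        ]
    sign = 1.0 if eta > 0 else -1.0
    return [(_outer_root(s, eta, sign), 1.0)]


@dataclass
class FixedPointStats:
    """Static self-consistent fixed-point statistics."""

    eta_var: float  # <eta^2> = g^2 C
    C: float  # sum_a n_a <phi(x_a)^2>
    branch: str
    stability_lhs: float = float("nan")


def _static_rhs(spec: SelfCouplingSpec, g: float, C: float, branch: str) -> float:
    """RHS of the self-consistency C = sum_a n_a <tanh^2 x_a(eta)>."""
    vals = np.asarray(spec.values, float)
    frac = np.asarray(spec.fractions, float)
    if C <= 0 or g == 0:
        total = 0.0
        for s_a, n_a in zip(vals, frac):
            total += n_a * sum(
                w * math.tanh(x) ** 2 for x, w in _branch_roots(s_a, 0.0, branch)
            )
        return total
    nodes, w = _gauss_hermite(g * math.sqrt(C))
    total = 0.0
    for s_a, n_a in zip(vals, frac):
        acc = 0.0
        for eta, wi in zip(nodes, w):
            acc += wi * sum(
                wb * math.tanh(x) ** 2 for x, wb in _branch_roots(s_a, eta, branch)
            )
        total += n_a * acc
    return total


def static_selfconsistent(
    spec: SelfCouplingSpec,
    g: float,
    branch: Literal["most_stable", "sampled"] = "most_stable",
) -> FixedPointStats:
    """Solve the static mean-field self-consistency <eta^2> = g^2 C.

    x_a(eta) is the chosen branch of x - s tanh x = eta; the Gaussian
    expectation over eta uses Gauss-Hermite quadrature.  Returns the
    largest self-consistent C (the trivial C=0 when no positive solution
    exists).
    """
    if spec.kind != "discrete":
        raise ValidationError("static solver requires a discrete spec")
    if g < 0:
        raise ValidationError("g must be non-negative")

    def psi(C: float) -> float:
        return _static_rhs(spec, g, C, branch) - C

    # scan from above: RHS <= 1 always, so root is in (0, 1]
    grid = np.linspace(1.0, 1e-6, 60)
    vals = [psi(c) for c in grid]
    C_star = 0.0
    for k in range(len(grid) - 1):
        if vals[k] == 0.0:
            C_star = grid[k]
            break
        if vals[k] * vals[k + 1] < 0:
            C_star = brentq(psi, grid[k + 1], grid[k], xtol=1e-12)
            break
    else:
        # no positive crossing: admit the trivial solution if consistent
        if abs(psi(0.0)) > 1e-9:
            raise ValidationError(
                "no self-consistent static solution found in (0, 1]"
            )
    stats = FixedPointStats(eta_var=g**2 * C_star, C=C_star, branch=branch)
    stats.stability_lhs = stability_lhs(stats, spec, g)
    return stats


def stability_lhs(
    stats: FixedPointStats, spec: SelfCouplingSpec, g: float
) -> float:
    """LHS of the fixed-point stability condition g^2 sum n_a <1/q_a> <= 1.

    q_a = [s_a - cosh^2 x_a]^2; on the most-stable (outer) branch q_a is
    bounded away from zero.  Inner-branch samples with vanishing q (the
    fold) would make the expectation diverge: such samples are excluded
    from the quadrature with their weight renormalized, mirroring the
    restriction of stable solutions to the outer intervals.
    """
    vals = np.asarray(spec.values, float)
    frac = np.asarray(spec.fractions, float)
    if stats.C <= 0 or g == 0:
        total = 0.0
        for s_a, n_a in zip(vals, frac):
            roots = _branch_roots(s_a, 0.0, stats.branch)
            total += n_a * sum(
                w / (s_a - math.cosh(x) ** 2) ** 2 for x, w in roots
            )
        return g**2 * total
    nodes, w = _gauss_hermite(g * math.sqrt(stats.C))
    total = 0.0
    for s_a, n_a in zip(vals, frac):
        acc = 0.0
        wsum = 0.0
        for eta, wi in zip(nodes, w):
            for x, wb in _branch_roots(s_a, eta, stats.branch):
                q = (s_a - math.cosh(x) ** 2) ** 2
                if q < 1e-14:
                    continue  # excluded-measure handling at the fold
                acc += wi * wb / q
                wsum += wi * wb
        if wsum > 0:
            acc /= wsum
        total += n_a * acc
    return g**2 * total


def classify_phase(
    spec: SelfCouplingSpec, g: float, branch: str = "most_stable"
) -> str:
    """'stable' if the most stable fixed point satisfies the stability
    condition (LHS <= 1), else 'chaotic'."""
    stats = static_selfconsistent(spec, g, branch=branch)
    return "stable" if stats.stability_lhs <= 1.0 else "chaotic"


def phase_boundary(
    s1_grid: np.ndarray,
    s2_grid: np.ndarray,
    n1: float,
    g: float,
    axis: int = 1,
) -> list[tuple[float, float]]:
    """Locate chaos/stability boundary points on a (s1, s2) grid.

    Scans lines of the grid along ``axis`` and bisects the stability-LHS
    crossing of 1 between adjacent grid points whose phase differs.
    Returns a list of (s1, s2) boundary points.
    """
    pts = []

    def lhs_at(s1: float, s2: float) -> float:
        spec = SelfCouplingSpec.two_populations(s1, s2, n1)
        return static_selfconsistent(spec, g).stability_lhs

    if axis == 1:
        lines = [(s1, np.asarray(s2_grid, float)) for s1 in np.atleast_1d(s1_grid)]
    else:
        lines = [(s2, np.asarray(s1_grid, float)) for s2 in np.atleast_1d(s2_grid)]
    for fixed, sweep in lines:
        vals = [lhs_at(fixed, sv) if axis == 1 else lhs_at(sv, fixed) for sv in sweep]
        for k in range(len(sweep) - 1):
            a, b = vals[k] - 1.0, vals[k + 1] - 1.0
            if a * b < 0:
                f = (
                    (lambda sv: lhs_at(fixed, sv) - 1.0)
                    if axis == 1
                    else (lambda sv: lhs_at(sv, fixed) - 1.0)
                )
                s_cross = brentq(f, sweep[k], sweep[k + 1], xtol=1e-4)
                pts.append(
                    (fixed, s_cross) if axis == 1 else (s_cross, fixed)
                )
    return pts


def critical_gain(
    spec: SelfCouplingSpec, g_lo: float = 0.05, g_hi: float = 4.0
) -> float:
    """Gain at which the most stable fixed point loses stability."""

    def f(g: float) -> float:
        return static_selfconsistent(spec, g).stability_lhs - 1.0

    return brentq(f, g_lo, g_hi, xtol=1e-5)
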