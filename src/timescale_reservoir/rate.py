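"""Random rate networks with heterogeneous self-couplings.

The model is a recurrent network of N rate units

    dx_i/dt = -x_i + s_i * phi(x_i) + g * sum_j J_ij phi(x_j) + I_i(t),

with phi = tanh, random couplings J_ij ~ N(0, 1/N) i.i.d. (zero diagonal),
gain g, and per-unit self-couplings s_i drawn from a distribution P(s).
Each unit is interpreted as a functional neural assembly whose self-coupling
represents assembly size (or mean intra-assembly coupling).  Time is measured
in units of the membrane time constant; per-unit time constants tau_i are
supported so that heterogeneity of single-unit integration timescales can be
studied in the same simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "SelfCouplingSpec",
    "RateNetwork",
    "Trajectory",
    "BroadbandStimulus",
    "sample_self_couplings",
    "build_network",
    "simulate",
    "make_broadband",
    "simulate_probe",
    "PHI",
]

#: transfer function of the rate units
PHI = np.tanh

#: default mapping from one model time unit (membrane time constant) to ms
DEFAULT_UNIT_TIME_MS = 3.0


class ValidationError(ValueError):
    """Raised on invalid model parameters or inputs."""


@dataclass(frozen=True)
class SelfCouplingSpec:
    """Distribution P(s) of unit self-couplings.

    kind='discrete' uses ``values`` with probabilities ``fractions``;
    'gaussian' and 'lognormal' use location ``mu`` and variance ``sigma2``
    (for the lognormal, parameters of log s).
    """

    kind: Literal["discrete", "gaussian", "lognormal"]
    values: Optional[Sequence[float]] = None
    fractions: Optional[Sequence[float]] = None
    mu: Optional[float] = None
    sigma2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "discrete":
            if self.values is None or self.fractions is None:
                raise ValidationError("discrete spec needs values and fractions")
            v = np.asarray(self.values, float)
            n = np.asarray(self.fractions, float)
            if v.size == 0 or v.size != n.size:
                raise ValidationError("values/fractions size mismatch or empty")
            if np.any(n < 0):
                raise ValidationError("fractions must be non-negative")
            if abs(n.sum() - 1.0) > 1e-12:
                raise ValidationError(
                    f"fractions must sum to 1 (got {n.sum():.16g})"
                )
        elif self.kind in ("gaussian", "lognormal"):
            if self.mu is None or self.sigma2 is None:
                raise ValidationError(f"{self.kind} spec needs mu and sigma2")
            if self.sigma2 <= 0:
                raise ValidationError("sigma2 must be positive")
        else:
            raise ValidationError(f"unknown spec kind {self.kind!r}")

    @staticmethod
    def degenerate(s: float) -> "SelfCouplingSpec":
        """All units share the single self-coupling value ``s``."""
        return SelfCouplingSpec("discrete", values=[s], fractions=[1.0])

    @staticmethod
    def two_populations(s1: float, s2: float, n1: float) -> "SelfCouplingSpec":
        return SelfCouplingSpec(
            "discrete", values=[s1, s2], fractions=[n1, 1.0 - n1]
        )


@dataclass
class RateNetwork:
    """A realized network: couplings, gain, self-couplings, time constants."""

    N: int
    g: float
    J: np.ndarray
    s: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValidationError("N must be >= 2")
        if np.any(self.tau <= 0):
            raise ValidationError("tau must be positive")


@dataclass
class Trajectory:
    """Uniformly sampled multivariate time series.

    ``x`` has shape (units, time); ``times`` is the sample grid.  ``burn_in``
    marks the initial duration to discard before computing statistics.
    """

    times: np.ndarray
    x: np.ndarray
    dt: float
    burn_in: float = 0.0

    def after_burn_in(self) -> np.ndarray:
        """Samples with t >= burn_in, shape (units, time)."""
        k = int(np.searchsorted(self.times, self.burn_in - 1e-12))
        return self.x[:, k:]


@dataclass
class BroadbandStimulus:
    """Superposition of L sinusoids with unit-specific random phases.

    The drive to unit i is  A * sum_l sin(2 pi f_l t_ms / 1000 + theta_il),
    with t_ms = t * unit_time_ms mapping model time to physical time.
    """

    freqs_hz: np.ndarray
    A: float
    phases: np.ndarray  # (n_units, L)
    unit_time_ms: float = DEFAULT_UNIT_TIME_MS

    def __call__(self, t: float) -> np.ndarray:
        t_s = t * self.unit_time_ms / 1000.0
        arg = 2.0 * np.pi * self.freqs_hz[None, :] * t_s + self.phases
        return self.A * np.sin(arg).sum(axis=1)


def sample_self_couplings(
    spec: SelfCouplingSpec, n: int, seed: int
) -> np.ndarray:
    """Draw ``n`` self-couplings from ``spec``.

    Discrete specs use largest-remainder apportionment so the realized
    composition matches round(n * n_alpha) exactly, then shuffle by seed.
    Continuous specs are i.i.d. draws.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    rng = np.random.default_rng(seed)
    if spec.kind == "discrete":
        vals = np.asarray(spec.values, float)
        frac = np.asarray(spec.fractions, float)
        quota = n * frac
        counts = np.floor(quota).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(quota - counts))  # largest remainders first
        counts[order[:rem]] += 1
        s = np.repeat(vals, counts)
        rng.shuffle(s)
        return s
    if spec.kind == "gaussian":
        return spec.mu + math.sqrt(spec.sigma2) * rng.standard_normal(n)
    # lognormal
    return np.exp(spec.mu + math.sqrt(spec.sigma2) * rng.standard_normal(n))


def build_network(
    N: int,
    g: float,
    spec: SelfCouplingSpec,
    seed: int,
    tau: Optional[np.ndarray] = None,
) -> RateNetwork:
    """Build a reproducible network realization.

    J entries are i.i.d. N(0, 1/N) off the diagonal; the diagonal is zero
    and the self-coupling enters separately through ``s``.
    """
    if N < 2:
        raise ValidationError("N must be >= 2")
    root = np.random.SeedSequence(seed)
    seed_J, seed_s = root.spawn(2)
    rng = np.random.default_rng(seed_J)
    J = rng.standard_normal((N, N)) / math.sqrt(N)
    np.fill_diagonal(J, 0.0)
    s = sample_self_couplings(spec, N, int(seed_s.generate_state(1)[0] % (2**31)))
    if tau is None:
        tau = np.ones(N)
    tau = np.asarray(tau, float)
    if tau.shape != (N,):
        raise ValidationError("tau must have shape (N,)")
    return RateNetwork(N=N, g=g, J=J, s=s, tau=tau)


def simulate(
    net: RateNetwork,
    duration: float,
    dt: float = 0.05,
    x0: Optional[np.ndarray] = None,
    drive: Optional[Callable[[float], np.ndarray]] = None,
    seed: Optional[int] = None,
    burn_in: Optional[float] = None,
    record_stride: int = 1,
) -> Trajectory:
    """Integrate the network ODE with explicit Euler.

    ``drive(t)`` (if given) returns the per-unit external input at model time
    t.  ``seed`` only controls the default initial condition (i.i.d. uniform
    on [-1, 1]) when ``x0`` is not supplied.  ``record_stride`` subsamples
    the stored trajectory (the integration step is always ``dt``).
    """
    if dt > 0.1:
        raise ValidationError("dt must be <= 0.1 model time units")
    if duration < dt:
        raise ValidationError("duration must be >= dt")
    N = net.N
    if x0 is None:
        rng = np.random.default_rng(0 if seed is None else seed)
        x = rng.uniform(-1.0, 1.0, N)
    else:
        x = np.array(x0, float, copy=True)
        if x.shape != (N,):
            raise ValidationError("x0 must have shape (N,)")
    nsteps = int(round(duration / dt))
    nrec = nsteps // record_stride
    out = np.empty((N, nrec))
    inv_tau = 1.0 / net.tau
    gJ = net.g * net.J
    s = net.s
    krec = 0
    for t in range(nsteps):
        phi = np.tanh(x)
        dxdt = -x + s * phi + gJ @ phi
        if drive is not None:
            dxdt = dxdt + drive(t * dt)
        x = x + dt * inv_tau * dxdt
        if (t + 1) % record_stride == 0:
            if not np.all(np.isfinite(x)):
                bad = int(np.nonzero(~np.isfinite(x))[0][0])
                raise FloatingPointError(
                    f"non-finite state at step {t} (t={t * dt:.3f}), "
                    f"first offending unit {bad}"
                )
            out[:, krec] = x
            krec += 1
    dt_rec = dt * record_stride
    times = (np.arange(nrec) + 1) * dt_rec
    if burn_in is None:
        burn_in = max(0.2 * duration, 50.0)
        burn_in = min(burn_in, 0.5 * duration)
    return Trajectory(times=times, x=out, dt=dt_rec, burn_in=burn_in)


def make_broadband(
    freqs_hz: Sequence[float],
    A: float,
    n_units: int,
    unit_time_ms: float = DEFAULT_UNIT_TIME_MS,
    seed: int = 0,
) -> BroadbandStimulus:
    """Broadband drive: equal-amplitude sinusoids with i.i.d. uniform phases."""
    freqs = np.asarray(freqs_hz, float)
    if n_units < 1:
        raise ValidationError("n_units must be >= 1")
    if np.any(freqs <= 0):
        raise ValidationError("frequencies must be positive")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, (n_units, freqs.size))
    return BroadbandStimulus(
        freqs_hz=freqs, A=A, phases=phases, unit_time_ms=unit_time_ms
    )


def white_noise_increments(
    D: float, g: float, dt: float, nsteps: int, rng: np.random.Generator
) -> np.ndarray:
    """Euler increments of white input with strength matching a colored
    noise of integrated autocorrelation D: variance g^2 * 2 D * dt per step."""
    return g * math.sqrt(2.0 * D * dt) * rng.standard_normal(nsteps)


def simulate_probe(
    s: float,
    noise: np.ndarray | tuple[float, float],
    duration: float,
    dt: float = 0.05,
    seed: int = 0,
    x0: float = 0.0,
    burn_in: float = 0.0,
) -> Trajectory:
    """Integrate a single probe unit dx/dt = -x + s phi(x) + input.

    ``noise`` is either a pre-sampled colored path (array on the same dt
    grid, length >= duration/dt) or a tuple (D, g) requesting white noise
    with increments of variance g^2 * 2 D * dt, so the injected input has
    integrated autocorrelation g^2 D.
    """
    nsteps = int(round(duration / dt))
    if isinstance(noise, tuple):
        D, g = noise
        if D <= 0:
            raise ValidationError("white-noise strength D must be positive")
        rng = np.random.default_rng(seed)
        incr = white_noise_increments(D, g, dt, nsteps, rng)
        white = True
    else:
        path = np.asarray(noise, float)
        if path.size < nsteps:
            raise ValidationError(
                f"noise path length {path.size} < required {nsteps}"
            )
        incr = path[:nsteps] * dt
        white = False
    x = float(x0)
    out = np.empty(nsteps)
    for t in range(nsteps):
        x = x + dt * (-x + s * math.tanh(x)) + incr[t]
        out[t] = x
    if not np.all(np.isfinite(out)):
        bad = int(np.nonzero(~np.isfinite(out))[0][0])
        raise FloatingPointError(f"non-finite probe state at step {bad}")
    times = (np.arange(nsteps) + 1) * dt
    return Trajectory(times=times, x=out[None, :], dt=dt, burn_in=burn_in)
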