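"""Unified colored-noise approximation (UCNA) for a slow bistable probe.

A probe unit with strong self-coupling s > 1, driven by Gaussian colored
noise of strength D and correlation timescale tau1, obeys

    dx/dt = f(x) + eta(t),      f(x) = -x + s tanh(x).

The UCNA closure of the Fokker-Planck equation yields the stationary law

    p(x) = Z^-1 |h(x)| exp[-U_eff(x) / D],    h(x) = 1 - tau1 f'(x),

with effective potential

    U_eff(x) = x^2/2 - s log cosh x + (tau1/2) f(x)^2 - U_min,

supported on the two disjoint intervals |x| > x_c where h > 0,

    tanh^2(x_c) = 1 - (1 + tau1) / (tau1 s).

The mean escape time out of a well is computed three ways: the exact
double-integral, its steepest-descent (small-D) evaluation, and the
large-s asymptotic  log<T> ~ (tau1 + 1)/(2D) * (s^2 - s log s).

When the noise is the self-consistent mean field of a network with
population autocorrelation C, ``D`` is the noise strength defined as
int_0^inf C dtau and ``tau1`` the HWHM timescale of C.  This pairing is
validated against simulated probe dwell times (see the test suite); the
gain factor of the mean field is not folded into D.  tau1 = 0 recovers
the white-noise (naive potential) limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, quad
from scipy.optimize import brentq, minimize_scalar

from .rate import ValidationError

__all__ = [
    "UCNAModel",
    "effective_potential",
    "support_edge",
    "stationary_density",
    "mfpt",
]


def _f(x: np.ndarray, s: float) -> np.ndarray:
    return -x + s * np.tanh(x)


def _fprime(x: np.ndarray, s: float) -> np.ndarray:
    return -1.0 + s / np.cosh(x) ** 2


def _positive_well(s: float) -> float:
    """Positive root of x = s tanh x (the well center, ~ s for large s)."""
    if s <= 1.0:
        return 0.0
    return brentq(lambda x: x - s * math.tanh(x), 1e-8, s + 1.0, xtol=1e-14)


def support_edge(s: float, tau1: float) -> float:
    """Edge x_c of the UCNA support |x| > x_c.

    tanh^2(x_c) = 1 - (1 + tau1)/(tau1 s); returns 0 (full support) when
    tau1 * s <= 1 + tau1.
    """
    if tau1 <= 0 or tau1 * s <= 1.0 + tau1:
        return 0.0
    t2 = 1.0 - (1.0 + tau1) / (tau1 * s)
    return math.atanh(math.sqrt(t2))


def effective_potential(
    x: np.ndarray, s: float, tau1: float, u_min: float = 0.0
):
    """U_eff(x) and its first two derivatives (analytic).

    U_eff = x^2/2 - s log cosh x + (tau1/2) f(x)^2 - u_min;
    U_eff' = -f h,  U_eff'' = -f' h - f h'  with h = 1 - tau1 f'.
    tau1 = 0 reduces to the naive white-noise potential.
    """
    x = np.asarray(x, float)
    f = _f(x, s)
    fp = _fprime(x, s)
    h = 1.0 - tau1 * fp
    U = 0.5 * x**2 - s * np.log(np.cosh(x)) + 0.5 * tau1 * f**2 - u_min
    U1 = -f * h
    hp = -tau1 * (-2.0 * s * np.tanh(x) / np.cosh(x) ** 2)
    U2 = -fp * h - f * hp
    return U, U1, U2


@dataclass
class UCNAModel:
    """Probe self-coupling s, noise color tau1, noise strength D."""

    s: float
    tau1: float
    D: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValidationError("noise strength D must be positive")
        if self.tau1 < 0:
            raise ValidationError("tau1 must be non-negative")
        self.xc = support_edge(self.s, self.tau1)
        self.x_plus = _positive_well(self.s)
        self.x_minus = -self.x_plus
        # normalize the potential so its minimum on the support is zero
        U_raw, _, _ = effective_potential(
            np.array([self.x_plus]), self.s, self.tau1
        )
        self.u_min = float(U_raw[0])

    def h(self, x: np.ndarray) -> np.ndarray:
        return 1.0 - self.tau1 * _fprime(np.asarray(x, float), self.s)

    def potential(self, x: np.ndarray):
        return effective_potential(x, self.s, self.tau1, u_min=self.u_min)

    def unnormalized_density(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        U, _, _ = self.potential(x)
        p = np.abs(self.h(x)) * np.exp(-U / self.D)
        p[np.abs(x) < self.xc] = 0.0
        return p


def stationary_density(model: UCNAModel, x: np.ndarray) -> np.ndarray:
    """Normalized stationary density on the given grid.

    Zero inside |x| <= x_c; the normalization constant is computed by
    adaptive quadrature over the support, so the returned values integrate
    to 1 over the full line regardless of the grid.
    """
    x = np.asarray(x, float)
    xmax = model.x_plus + max(
        8.0 * math.sqrt(model.D / max(model.s, 1.0)), 6.0
    )
    Z_half, _ = quad(
        lambda t: float(model.unnormalized_density(np.array([t]))[0]),
        model.xc,
        xmax,
        epsabs=1e-12,
        epsrel=1e-9,
        limit=400,
    )
    return model.unnormalized_density(x) / (2.0 * Z_half)


def _rho(model: UCNAModel, x: np.ndarray) -> np.ndarray:
    """Outer-integrand exponent rho(x) = U_eff(x) + D log|h(x)|."""
    U, _, _ = model.potential(np.asarray(x, float))
    return U + model.D * np.log(np.abs(model.h(x)))


def _locate_xf(model: UCNAModel) -> float:
    """Maximizer of rho on (x_minus, -x_c): the escape bottleneck -x_f.

    tanh^2(x_f) ~ 1 - 1/(2 s) provides the initial bracket only.
    """
    a, b = model.x_minus + 1e-6, -model.xc - 1e-9
    res = minimize_scalar(
        lambda x: -float(_rho(model, np.array([x]))[0]),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def mfpt(model: UCNAModel, method: str = "integral") -> float:
    """Mean first-passage time out of a well (log T for 'asymptotic').

    integral:
        <T> = (1/D) * int_{x_-}^{-x_c} dx |h| e^{U_eff/D}
                    * int_{-inf}^{x} p(y) dy
        with the inner CDF tabulated on a fine grid.
    steepest:
        <T> ~ 2 pi / sqrt(U_eff''(x_-) |rho''(x_f)|) * exp(Delta / D),
        Delta = rho(x_f) - U_eff(x_-),  rho = U_eff + D log|h|.
    asymptotic (returns log<T>):
        (tau1 + 1) / (2 D) * (s^2 - s log s),  requires s > 1.
    """
    s, tau1, D = model.s, model.tau1, model.D
    if method == "asymptotic":
        if s <= 1:
            raise ValidationError("asymptotic form requires s > 1")
        return (tau1 + 1.0) / (2.0 * D) * (s**2 - s * math.log(s))

    if model.x_plus <= model.xc:
        raise ValidationError("no well outside the support edge")

    if method == "steepest":
        _, _, U2m = model.potential(np.array([model.x_minus]))
        xf = _locate_xf(model)
        # numerical second derivative of rho at xf
        eps = 1e-5 * max(1.0, abs(xf))
        r = _rho(model, np.array([xf - eps, xf, xf + eps]))
        rho2 = (r[0] - 2.0 * r[1] + r[2]) / eps**2
        Um, _, _ = model.potential(np.array([model.x_minus]))
        delta = float(r[1] - Um[0])
        # Laplace evaluation of the inner integral carries the density
        # prefactor |h(x_-)| ~ 1 + tau1 at the well bottom
        h_m = abs(float(model.h(np.array([model.x_minus]))[0]))
        pref = 2.0 * math.pi * h_m / math.sqrt(float(U2m[0]) * abs(rho2))
        return pref * math.exp(delta / D)

    if method != "integral":
        raise ValidationError(f"unknown MFPT method {method!r}")

    # ---- exact double integral ----
    xmax = model.x_plus + max(8.0 * math.sqrt(D / max(s, 1.0)), 6.0)
    # inner CDF over the left support interval (-xmax, -xc); by symmetry
    # the mass below any x in that interval comes from that interval only
    grid = np.linspace(-xmax, -model.xc, 4001)
    p_un = model.unnormalized_density(grid)
    cdf_un = np.concatenate(
        [[0.0], cumulative_trapezoid(p_un, grid)]
    )
    Z = 2.0 * cdf_un[-1]
    if Z <= 0 or not np.isfinite(Z):
        raise FloatingPointError(
            "density normalization failed on the support"
        )

    def inner_cdf_unnorm(x: float) -> float:
        return float(np.interp(x, grid, cdf_un))

    def outer_integrand(x: float) -> float:
        # 1/(B p) with B = D/h^2 gives (Z/D) |h| e^{U/D}; the Z from the
        # outer 1/p and the 1/Z of the inner CDF cancel, so the
        # unnormalized CDF is used directly
        xv = np.array([x])
        U, _, _ = model.potential(xv)
        return (
            abs(float(model.h(xv)[0]))
            * math.exp(float(U[0]) / D)
            * inner_cdf_unnorm(x)
        )

    val, err = quad(
        outer_integrand,
        model.x_minus,
        -model.xc,
        epsabs=1e-10,
        epsrel=1e-8,
        limit=400,
    )
    if not np.isfinite(val) or (val > 0 and err / max(val, 1e-300) > 1e-2):
        raise FloatingPointError(
            f"outer quadrature unreliable on ({model.x_minus:.3f}, "
            f"{-model.xc:.3f}): value {val:.3e}, error {err:.3e}"
        )
    return val / D
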