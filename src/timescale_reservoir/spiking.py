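"""Clustered excitatory-inhibitory spiking networks.

Current-based leaky integrate-and-fire (LIF) network with E and I
populations arranged in paired assemblies: intra-assembly synapses are
potentiated (factors J+), inter-assembly synapses depressed (factors J-),
and a fraction of each population remains unclustered background.  The
module also implements the two-population LIF mean-field transfer (with the
Brunel-Sergi synaptic-filtering correction), threshold calibration to
target balanced-state rates, the mapping from assembly size to an effective
self-coupling s_i = C_i * pEE * JEE * JEE+ (mV), assembly activation-time
statistics, cross-validated polynomial fitting of log dwell time versus
self-coupling, and the (2p+2)-population mean-field-reduced weight matrix
with its eigen/Schur analysis.

Weight magnitudes follow the balanced-network convention j / sqrt(2 N) mV;
with the default parameters the homogeneous network sits at rates
(rE, rI) = (2, 5) spk/s for thresholds (1.43, 0.74) mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from numba import njit
from scipy.integrate import quad
from scipy.linalg import eig
from scipy.optimize import brentq, root
from scipy.special import erfcx, zeta

from .rate import ValidationError

__all__ = [
    "SpikingParams",
    "SpikingNetwork",
    "SpikeData",
    "AssemblyActivation",
    "derive_clustered_params",
    "build_spiking_network",
    "simulate_lif",
    "lif_transfer_rate",
    "mf_rates_homogeneous",
    "calibrate_thresholds",
    "assembly_self_couplings",
    "assembly_activation_times",
    "fit_dwell_vs_selfcoupling",
    "reduced_weight_matrix",
    "spectra",
    "schur_modes",
]

#: Brunel-Sergi constant |zeta(1/2)|/sqrt(2) of the synaptic-filtering
#: threshold shift a*k, k = sqrt(tau_s/tau_m).
A_BRUNEL_SERGI = abs(zeta(0.5)) / math.sqrt(2.0)
#: alternative printed reading |zeta(1/2)|/2
A_BRUNEL_SERGI_HALF = abs(zeta(0.5)) / 2.0


@dataclass
class SpikingParams:
    """Base parameters of the clustered network (weights in mV, times ms).

    Weight entries j_* are dimensionless table values; realized synaptic
    weights are j / sqrt(2 N) mV.  Potentiation factors and the E-I
    potentiation parameters scale linearly with N/2000.
    """

    N: int = 2000
    nE: float = 0.8
    nI: float = 0.2
    nbgr: float = 0.1
    pEE: float = 0.2
    pEI: float = 0.5
    pIE: float = 0.5
    pII: float = 0.5
    jEE: float = 0.9
    jIE: float = 0.9
    jEI: float = 2.7
    jII: float = 5.4
    jE0: float = 3.7
    jI0: float = 3.3
    jEE_plus: float = 14.0  # at N=2000; scales as N/2000
    jII_plus: float = 5.0
    gEI: float = 10.0
    gIE: float = 8.0
    rext: float = 5.0  # spk/s per afferent
    VEthr: float = 1.43  # mV
    VIthr: float = 0.74
    Vreset: float = 0.0
    tau_m: float = 20.0  # ms
    tau_refr: float = 5.0
    tau_s: float = 5.0
    a_bs: float = A_BRUNEL_SERGI
    ext_variance: bool = False  # constant external current by default

    def __post_init__(self) -> None:
        if not (0 <= self.nbgr < 1):
            raise ValidationError("nbgr must be in [0, 1)")
        for p in (self.pEE, self.pEI, self.pIE, self.pII):
            if not (0 <= p <= 1):
                raise ValidationError("connection probabilities must be in [0,1]")

    # --- derived scalars -------------------------------------------------
    @property
    def weight_scale(self) -> float:
        return 1.0 / math.sqrt(2.0 * self.N)

    @property
    def NE(self) -> int:
        return int(round(self.nE * self.N))

    @property
    def NI(self) -> int:
        return int(round(self.nI * self.N))

    @property
    def Next(self) -> float:
        return self.nE * self.N * self.pEE

    @property
    def JEE(self) -> float:
        return self.jEE * self.weight_scale

    @property
    def JIE(self) -> float:
        return self.jIE * self.weight_scale

    @property
    def JEI(self) -> float:
        return self.jEI * self.weight_scale

    @property
    def JII(self) -> float:
        return self.jII * self.weight_scale

    @property
    def JE0(self) -> float:
        return self.jE0 * self.weight_scale

    @property
    def JI0(self) -> float:
        return self.jI0 * self.weight_scale

    @property
    def NEclust_mean(self) -> float:
        return 60.0 + self.N / 100.0


@dataclass
class ClusteredParams:
    """Derived clustered-architecture quantities."""

    base: SpikingParams
    p: int
    sizes_E: np.ndarray
    sizes_I: np.ndarray
    f: float
    gamma: float
    JEE_plus: float
    JEE_minus: float
    JII_plus: float
    JII_minus: float
    JEI_plus: float
    JEI_minus: float
    JIE_plus: float
    JIE_minus: float


@dataclass
class SpikingNetwork:
    """Realized network: weights (mV), cell types, assembly membership."""

    params: SpikingParams
    W: np.ndarray  # (post, pre), signed
    is_E: np.ndarray  # bool per neuron
    membership: np.ndarray  # 0 = background, 1..p assemblies
    clustered: Optional[ClusteredParams] = None


@dataclass
class SpikeData:
    """Spike events (times ms, neuron ids), time-sorted."""

    times: np.ndarray
    ids: np.ndarray
    duration: float
    dt: float


@dataclass
class AssemblyActivation:
    """Binary activation series and interval statistics of one assembly."""

    assembly: int
    active: np.ndarray  # bool per bin
    bin_ms: float
    intervals: np.ndarray  # activation durations, ms
    mean_T: float
    s_E: float
    flagged: bool = False  # never active / degenerate rate range


def derive_clustered_params(
    base: SpikingParams, seed: int
) -> ClusteredParams:
    """Assembly count, heterogeneous sizes, and potentiation/depression.

    Sizes are uniform with mean NEclust = 60 + N/100 and 30% SD, rounded;
    the largest assembly absorbs the rounding remainder so clustered totals
    equal nE N (1 - nbgr) exactly.  Depression factors follow
    J-aa = 1 - gamma (J+aa - 1) with gamma = f (2 - f (p + 1)), and
    JEI+ = p / (1 + (p-1)/gEI) (likewise IE), JEI- = JEI+/gEI.
    """
    if base.N < 1000:
        raise ValidationError("clustered architecture requires N >= 1000")
    scale = base.N / 2000.0
    p = int(round(base.nE * base.N * (1 - base.nbgr) / base.NEclust_mean))
    if p < 2:
        raise ValidationError(f"derived assembly count p={p} < 2")
    f = (1 - base.nbgr) / p
    rng = np.random.default_rng(seed)
    half_width = math.sqrt(3.0) * 0.3  # uniform with 30% SD
    lo = base.NEclust_mean * (1 - half_width)
    hi = base.NEclust_mean * (1 + half_width)
    sizes = np.round(rng.uniform(lo, hi, p)).astype(int)
    target = int(round(base.nE * base.N * (1 - base.nbgr)))
    # spread the rounding remainder one neuron at a time (largest first)
    # so realized sizes stay inside the drawn uniform range
    rem = target - sizes.sum()
    order = np.argsort(-sizes)
    step = 1 if rem > 0 else -1
    for k in range(abs(rem)):
        sizes[order[k % p]] += step
    sizes_I = np.round(sizes * base.nI / base.nE).astype(int)

    jEEp = base.jEE_plus * scale
    jIIp = base.jII_plus * scale
    gEI = base.gEI * scale
    gIE = base.gIE * scale
    JEIp = p / (1 + (p - 1) / gEI)
    JIEp = p / (1 + (p - 1) / gIE)
    gamma = f * (2 - f * (p + 1))
    return ClusteredParams(
        base=base,
        p=p,
        sizes_E=sizes,
        sizes_I=sizes_I,
        f=f,
        gamma=gamma,
        JEE_plus=jEEp,
        JEE_minus=1 - gamma * (jEEp - 1),
        JII_plus=jIIp,
        JII_minus=1 - gamma * (jIIp - 1),
        JEI_plus=JEIp,
        JEI_minus=JEIp / gEI,
        JIE_plus=JIEp,
        JIE_minus=JIEp / gIE,
    )


def _membership(cl: ClusteredParams) -> tuple[np.ndarray, np.ndarray]:
    base = cl.base
    membE = np.zeros(base.NE, int)
    i0 = 0
    for a, sz in enumerate(cl.sizes_E, 1):
        membE[i0 : i0 + sz] = a
        i0 += sz
    membI = np.zeros(base.NI, int)
    i0 = 0
    for a, sz in enumerate(cl.sizes_I, 1):
        membI[i0 : i0 + sz] = a
        i0 += sz
    return membE, membI


def build_spiking_network(
    params: SpikingParams,
    seed: int,
    clustered: bool = True,
) -> SpikingNetwork:
    """Erdos-Renyi connectivity with type- and assembly-dependent weights.

    Weight from pre j to post i is the base J (sign: E positive, I
    negative) times J+ if both neurons share an assembly, J- if both are
    clustered but in different assemblies, and 1 if either is background.
    """
    N = params.N
    NE, NI = params.NE, params.NI
    root_ss = np.random.SeedSequence(seed)
    ss_sizes, ss_conn = root_ss.spawn(2)
    is_E = np.zeros(N, bool)
    is_E[:NE] = True
    if clustered:
        cl = derive_clustered_params(
            params, int(ss_sizes.generate_state(1)[0] % (2**31))
        )
        membE, membI = _membership(cl)
        memb = np.concatenate([membE, membI])
    else:
        cl = None
        memb = np.zeros(N, int)
    rng = np.random.default_rng(ss_conn)
    pmat = np.empty((N, N))
    pmat[np.ix_(is_E, is_E)] = params.pEE
    pmat[np.ix_(is_E, ~is_E)] = params.pEI
    pmat[np.ix_(~is_E, is_E)] = params.pIE
    pmat[np.ix_(~is_E, ~is_E)] = params.pII
    mask = rng.random((N, N)) < pmat
    np.fill_diagonal(mask, False)

    W = np.zeros((N, N))
    base = np.empty((N, N))
    base[np.ix_(is_E, is_E)] = params.JEE
    base[np.ix_(is_E, ~is_E)] = -params.JEI
    base[np.ix_(~is_E, is_E)] = params.JIE
    base[np.ix_(~is_E, ~is_E)] = -params.JII
    fac = np.ones((N, N))
    if cl is not None:
        same = (memb[:, None] == memb[None, :]) & (memb[:, None] > 0)
        diff = (memb[:, None] > 0) & (memb[None, :] > 0) & ~same
        for post, pre, jp, jm in (
            (is_E, is_E, cl.JEE_plus, cl.JEE_minus),
            (is_E, ~is_E, cl.JEI_plus, cl.JEI_minus),
            (~is_E, is_E, cl.JIE_plus, cl.JIE_minus),
            (~is_E, ~is_E, cl.JII_plus, cl.JII_minus),
        ):
            blk = np.ix_(post, pre)
            fac[blk] = np.where(
                same[blk], jp, np.where(diff[blk], jm, 1.0)
            )
    W = np.where(mask, base * fac, 0.0)
    return SpikingNetwork(
        params=params, W=W, is_E=is_E, membership=memb, clustered=cl
    )


@njit(cache=True)
def _lif_kernel(W, Iext, vthr, v0, duration, dt, tau_m, tau_s, tau_refr):
    n = W.shape[0]
    V = v0.copy()
    Irec = np.zeros(n)
    refr = np.zeros(n)
    nsteps = int(duration / dt)
    spk_t = []
    spk_i = []
    for t in range(nsteps):
        inc = np.zeros(n)
        for i in range(n):
            if refr[i] > 0.0:
                refr[i] -= dt
                continue
            V[i] += dt * (-V[i] / tau_m + Irec[i] + Iext[i])
            if V[i] >= vthr[i]:
                spk_t.append((t + 1) * dt)
                spk_i.append(i)
                V[i] = 0.0
                refr[i] = tau_refr
                for j in range(n):
                    w = W[j, i]
                    if w != 0.0:
                        inc[j] += w
        bad = -1
        for i in range(n):
            Irec[i] += dt * (-Irec[i] / tau_s) + inc[i] / tau_s
            if not np.isfinite(V[i]):
                bad = i
        if bad >= 0:
            return (
                np.array(spk_t),
                np.array(spk_i, np.int64),
                t,
                bad,
            )
    return np.array(spk_t), np.array(spk_i, np.int64), -1, -1


def simulate_lif(
    net: SpikingNetwork,
    duration: float,
    dt: float = 0.05,
    seed: int = 0,
) -> SpikeData:
    """Clock-driven forward-Euler LIF simulation.

    A presynaptic spike increments the target's synaptic current by J/tau_s
    at the following step (exponential kernel with unit integral J).  The
    membrane is clamped at reset for tau_refr after each spike.  The seed
    only sets the initial membrane potentials (uniform on [0, V_thr)).
    """
    if dt > 0.1:
        raise ValidationError("dt must be <= 0.1 ms")
    pr = net.params
    Iext = np.where(
        net.is_E,
        pr.Next * pr.JE0 * pr.rext / 1000.0,  # mV/ms
        pr.Next * pr.JI0 * pr.rext / 1000.0,
    )
    vthr = np.where(net.is_E, pr.VEthr, pr.VIthr)
    rng = np.random.default_rng(seed)
    v0 = rng.uniform(0.0, 1.0, net.W.shape[0]) * vthr
    spk_t, spk_i, bad_step, bad_i = _lif_kernel(
        net.W, Iext, vthr, v0, duration, dt, pr.tau_m, pr.tau_s, pr.tau_refr
    )
    if bad_step >= 0:
        raise FloatingPointError(
            f"non-finite membrane potential: neuron {bad_i} at step {bad_step}"
        )
    return SpikeData(times=spk_t, ids=spk_i, duration=duration, dt=dt)


# ---------------------------------------------------------------------------
# Mean-field transfer and calibration
# ---------------------------------------------------------------------------


def lif_transfer_rate(
    mu: float,
    sigma: float,
    vthr: float,
    params: SpikingParams,
) -> float:
    """LIF current-to-rate transfer with synaptic-filtering correction.

    F = [tau_refr + tau_m sqrt(pi) * int_H^Theta e^{u^2}(1 + erf u) du]^-1
    with H = (Vreset - mu)/sigma + a k, Theta = (Vthr - mu)/sigma + a k,
    k = sqrt(tau_s/tau_m).  mu is the stationary mean membrane potential
    (mV), sigma its dispersion (mV).  The integrand e^{u^2}(1+erf u) equals
    erfcx(-u), numerically stable on both tails; far-subthreshold inputs
    return rate 0 rather than overflowing.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    ak = params.a_bs * math.sqrt(params.tau_s / params.tau_m)
    H = (params.Vreset - mu) / sigma + ak
    Th = (vthr - mu) / sigma + ak
    if Th > 26.0:
        # erfcx(-u) ~ 2 e^{u^2}: integral beyond float range -> rate ~ 0
        return 0.0
    val, _ = quad(lambda u: erfcx(-u), H, Th, limit=200)
    # tau_m, tau_refr in ms -> rate in spk/s
    return 1000.0 / (params.tau_refr + params.tau_m * math.sqrt(math.pi) * val)


def _homog_mu_sigma(params: SpikingParams, rE: float, rI: float):
    """Stationary mean/dispersion of membrane potential, homogeneous net.

    mu = tau_m * (sum_pre N_pre p J r_pre + I_ext), with rates in spk/s and
    tau_m in seconds; sigma^2 = tau_m * sum_pre N_pre p J^2 r_pre (the
    constant external current contributes no variance unless
    params.ext_variance is set).
    """
    tm = params.tau_m / 1000.0
    NE, NI = params.NE, params.NI
    kEE = NE * params.pEE * params.JEE
    kEI = NI * params.pEI * params.JEI
    kIE = NE * params.pIE * params.JIE
    kII = NI * params.pII * params.JII
    muE = tm * (kEE * rE - kEI * rI + params.Next * params.JE0 * params.rext)
    muI = tm * (kIE * rE - kII * rI + params.Next * params.JI0 * params.rext)
    s2E = tm * (
        NE * params.pEE * params.JEE**2 * rE
        + NI * params.pEI * params.JEI**2 * rI
    )
    s2I = tm * (
        NE * params.pIE * params.JIE**2 * rE
        + NI * params.pII * params.JII**2 * rI
    )
    if params.ext_variance:
        s2E += tm * params.Next * params.JE0**2 * params.rext
        s2I += tm * params.Next * params.JI0**2 * params.rext
    return (muE, muI), (math.sqrt(s2E), math.sqrt(s2I))


def mf_rates_homogeneous(
    params: SpikingParams,
    r0: tuple[float, float] = (2.0, 5.0),
    damping: float = 0.3,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[float, float]:
    """Self-consistent (rE, rI) of the homogeneous two-population network.

    Damped fixed-point iteration of r <- F(mu(r), sigma(r)) followed by a
    root polish; raises with the residuals on non-convergence.
    """
    r = np.array(r0, float)
    for _ in range(max_iter):
        (muE, muI), (sE, sI) = _homog_mu_sigma(params, *np.maximum(r, 0.0))
        F = np.array(
            [
                lif_transfer_rate(muE, sE, params.VEthr, params),
                lif_transfer_rate(muI, sI, params.VIthr, params),
            ]
        )
        r_new = (1 - damping) * r + damping * F
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new

    def resid(rv):
        (muE, muI), (sE, sI) = _homog_mu_sigma(params, *np.maximum(rv, 0.0))
        return [
            lif_transfer_rate(muE, sE, params.VEthr, params) - rv[0],
            lif_transfer_rate(muI, sI, params.VIthr, params) - rv[1],
        ]

    sol = root(resid, r, method="hybr")
    if not sol.success:
        raise RuntimeError(
            f"mean-field fixed point did not converge: residuals {sol.fun}"
        )
    return float(sol.x[0]), float(sol.x[1])


def calibrate_thresholds(
    params: SpikingParams, target: tuple[float, float] = (2.0, 5.0)
) -> tuple[float, float]:
    """Thresholds (VEthr, VIthr) putting the homogeneous net at the target
    rates: mu and sigma follow from the target rates directly, then each
    threshold is solved by 1-D root finding."""
    rE, rI = target
    (muE, muI), (sE, sI) = _homog_mu_sigma(params, rE, rI)
    vE = brentq(
        lambda v: lif_transfer_rate(muE, sE, v, params) - rE, 1e-3, 30.0
    )
    vI = brentq(
        lambda v: lif_transfer_rate(muI, sI, v, params) - rI, 1e-3, 30.0
    )
    return float(vE), float(vI)


# ---------------------------------------------------------------------------
# Assembly self-couplings and activation statistics
# ---------------------------------------------------------------------------


def assembly_self_couplings(
    net: SpikingNetwork, empirical: bool = False
) -> np.ndarray:
    """Effective self-coupling s_i = C_i^E pEE JEE JEE+ (mV) per assembly.

    With ``empirical=True`` the product pEE JEE JEE+ is replaced by the
    realized mean intra-assembly E-to-E weight (including the Erdos-Renyi
    dilution), s_i = C_i^E * mean_in-assembly(W).
    """
    if net.clustered is None:
        raise ValidationError("network has no assemblies")
    cl = net.clustered
    pr = net.params
    if not empirical:
        return cl.sizes_E * pr.pEE * pr.JEE * cl.JEE_plus
    s = np.empty(cl.p)
    for a in range(1, cl.p + 1):
        ids = np.nonzero((net.membership == a) & net.is_E)[0]
        blk = net.W[np.ix_(ids, ids)]
        off = ~np.eye(ids.size, dtype=bool)
        s[a - 1] = ids.size * blk[off].mean()
    return s


def assembly_activation_times(
    spikes: SpikeData,
    net: SpikingNetwork,
    bin_ms: float = 25.0,
    threshold: Literal["percentile", "fixed"] = "percentile",
    fixed_rate_hz: float = 10.0,
) -> list[AssemblyActivation]:
    """Per-assembly activation intervals from binned firing rates.

    Each assembly's population rate is binned at ``bin_ms`` and binarized:
    with the 'percentile' policy the threshold is the midpoint of the 10th
    and 90th percentiles of its binned rate (assemblies whose rate range
    never separates are flagged); 'fixed' thresholds at ``fixed_rate_hz``.
    Incomplete first/last activations are kept (they lower-bound the true
    dwell; censoring at the epoch edge is inherent to finite simulations).
    """
    if spikes.duration < 10 * bin_ms:
        raise ValidationError("duration must be >= 10 bins")
    if net.clustered is None:
        raise ValidationError("network has no assemblies")
    cl = net.clustered
    s_vec = assembly_self_couplings(net)
    edges = np.arange(0.0, spikes.duration + bin_ms / 2, bin_ms)
    out = []
    for a in range(1, cl.p + 1):
        ids = np.nonzero((net.membership == a) & net.is_E)[0]
        m = np.isin(spikes.ids, ids)
        counts, _ = np.histogram(spikes.times[m], edges)
        rate = counts / ids.size / (bin_ms / 1000.0)
        if threshold == "percentile":
            q10, q90 = np.percentile(rate, [10, 90])
            thr = 0.5 * (q10 + q90)
            flagged = (q90 - q10) < 1.0  # no bimodal separation
        else:
            thr = fixed_rate_hz
            flagged = False
        active = rate > thr
        if not active.any():
            out.append(
                AssemblyActivation(
                    assembly=a,
                    active=active,
                    bin_ms=bin_ms,
                    intervals=np.array([]),
                    mean_T=float("nan"),
                    s_E=float(s_vec[a - 1]),
                    flagged=True,
                )
            )
            continue
        d = np.diff(active.astype(int))
        starts = np.nonzero(d == 1)[0] + 1
        ends = np.nonzero(d == -1)[0] + 1
        if active[0]:
            starts = np.r_[0, starts]
        if active[-1]:
            ends = np.r_[ends, active.size]
        durs = (ends - starts) * bin_ms
        out.append(
            AssemblyActivation(
                assembly=a,
                active=active,
                bin_ms=bin_ms,
                intervals=durs,
                mean_T=float(durs.mean()),
                s_E=float(s_vec[a - 1]),
                flagged=flagged,
            )
        )
    return out


def fit_dwell_vs_selfcoupling(
    s: np.ndarray,
    T: np.ndarray,
    max_degree: int = 5,
    split_seed: int = 0,
    n_splits: int = 25,
) -> dict:
    """Cross-validated polynomial fit of log T (natural log) versus s.

    The data are split into equal train/test halves; polynomials of degree
    1..max_degree are fit on the training half by least squares and scored
    by test MSE.  The split-and-score step is repeated ``n_splits`` times
    (splits derived from ``split_seed``); the selected degree is the
    smallest one whose averaged test MSE lies within one standard error of
    the overall minimum (the usual parsimony rule for noisy CV curves).
    Returned coefficients are refit on all data (numpy polyfit convention,
    highest degree first).
    """
    s = np.asarray(s, float)
    T = np.asarray(T, float)
    if s.size != T.size or s.size < 6:
        raise ValidationError("need >= 6 (s, T) pairs")
    if np.any(T <= 0):
        raise ValidationError("dwell times must be positive")
    y = np.log(T)
    rng = np.random.default_rng(split_seed)
    half = s.size // 2
    degrees = [d for d in range(1, max_degree + 1) if half > d]
    if not degrees:
        raise ValidationError("degenerate design: too few training points")
    acc = {d: [] for d in degrees}
    for _ in range(n_splits):
        idx = rng.permutation(s.size)
        tr, te = idx[:half], idx[half:]
        for deg in degrees:
            with np.errstate(all="ignore"):
                coef = np.polyfit(s[tr], y[tr], deg)
            pred = np.polyval(coef, s[te])
            acc[deg].append(float(np.mean((pred - y[te]) ** 2)))
    mses = {d: float(np.mean(m)) for d, m in acc.items()}
    d_star = min(mses, key=mses.get)
    se = float(np.std(acc[d_star]) / math.sqrt(n_splits))
    best = min(
        d for d, m in mses.items() if m <= mses[d_star] + se + 1e-12
    )
    coef_full = np.polyfit(s, y, best)
    return {
        "degree": best,
        "coefficients": coef_full,
        "test_mse": mses,
    }


# ---------------------------------------------------------------------------
# Mean-field-reduced weight matrix and Schur modes
# ---------------------------------------------------------------------------


def _population_index(net: SpikingNetwork) -> list[np.ndarray]:
    """Neuron index sets of the 2p+2 populations.

    Order: E clusters 1..p, E background, I clusters 1..p, I background.
    """
    if net.clustered is None:
        raise ValidationError("reduction requires a clustered network")
    p = net.clustered.p
    groups = []
    for a in range(1, p + 1):
        groups.append(np.nonzero(net.is_E & (net.membership == a))[0])
    groups.append(np.nonzero(net.is_E & (net.membership == 0))[0])
    for a in range(1, p + 1):
        groups.append(np.nonzero(~net.is_E & (net.membership == a))[0])
    groups.append(np.nonzero(~net.is_E & (net.membership == 0))[0])
    return groups


def reduced_weight_matrix(net: SpikingNetwork) -> np.ndarray:
    """(2p+2) mean-field matrix: average total input weight between
    populations, JMF[A, B] = N_B * mean(W[A-neurons, B-neurons])."""
    groups = _population_index(net)
    k = len(groups)
    JMF = np.empty((k, k))
    for a, ga in enumerate(groups):
        for b, gb in enumerate(groups):
            JMF[a, b] = net.W[np.ix_(ga, gb)].mean() * gb.size
    return JMF


def spectra(M: np.ndarray) -> np.ndarray:
    """Eigenvalues ordered by descending real part."""
    ev = eig(M, right=False)
    return ev[np.argsort(-ev.real)]


def schur_modes(JMF: np.ndarray, p: int, n_leading: Optional[int] = None) -> dict:
    """Schur basis of JMF ordered by descending eigenvalue real part.

    Constructed by QR-orthonormalizing the eigenvector matrix in that
    order: the span of the first k columns is the invariant subspace of the
    k leading eigenvalues, so Q* JMF Q is upper triangular with the
    eigenvalues on the diagonal in the requested order.  Each of the
    ``n_leading`` (default p-1) leading modes is mapped to the E/I cluster
    pair with maximal combined loading (population order: E clusters 1..p,
    E background, I clusters 1..p, I background).
    """
    ev, V = eig(JMF)
    order = np.argsort(-ev.real)
    Q, R = np.linalg.qr(V[:, order])
    T = Q.conj().T @ JMF @ Q
    diag = np.diag(T)
    if n_leading is None:
        n_leading = max(p - 1, 1)
    mapping = []
    for k in range(n_leading):
        v = Q[:, k]
        loads = np.abs(v[:p]) + np.abs(v[p + 1 : 2 * p + 1])
        mapping.append(int(np.argmax(loads)) + 1)
    return {"T": T, "modes": Q, "eigenvalues": diag, "cluster_map": mapping}
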