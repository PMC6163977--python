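"""Forward simulation of the candidate viscoelastic constitutive laws.

The experiment is a stress-controlled uniaxial test on a quasi-incompressible
soft-tissue sample: the applied stress ramps linearly from 0 to ``sigma_max``
over a half-duration ``T`` and back to 0 over the second half (a triangular
protocol), and the strain is recorded every ``dt_sample`` seconds.

Five model classes are considered, all scalar (work-conjugate stress/strain
pair) and all built from a nonlinear elastic spring in series with a dashpot
(Maxwell arrangement), so total strain is elastic plus viscous:

    H1  mu, eta, A        sigma = mu*e + A*e^2        de_v/dt = sigma/eta
    H2  mu, eta           sigma = mu*e                de_v/dt = sigma/eta
    H3  mu                sigma = mu*e                (no dashpot)
    H4  mu, eta, A, D     sigma = mu*e + A*e^2 + D*e^3
    H5  mu, A             H1 with an aging dashpot eta(t) = 3*mu*t

``A`` and ``D`` are Landau-type second/third-order elastic constants (Pa),
common in soft-tissue biomechanical characterization.  Because the applied
stress history is known, the dashpot rate ``sigma(t)/eta(t)`` never depends on
the state, and the viscous strain is a pure quadrature — integrated here with
the trapezoidal (Heun) rule on a fine internal grid.  H5's rate
``sigma/(3*mu*t)`` has a removable singularity at t = 0 (the loading ramp makes
it tend to ``sigma_max/(3*mu*T)``), which the quadrature uses as the t = 0
integrand value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "LoadProtocol",
    "MaterialParams",
    "HypothesisSpec",
    "StrainSeries",
    "HYPOTHESES",
    "PARAM_ORDER",
    "hypothesis",
    "stress_at",
    "elastic_strain",
    "simulate",
    "forward_batch",
    "count_samples",
]

PARAM_ORDER = ("mu", "eta", "A", "D")

#: Active parameters of each model class, in canonical order.
HYPOTHESES: dict[str, tuple[str, ...]] = {
    "H1": ("mu", "eta", "A"),
    "H2": ("mu", "eta"),
    "H3": ("mu",),
    "H4": ("mu", "eta", "A", "D"),
    "H5": ("mu", "A"),
}


@dataclass(frozen=True)
class HypothesisSpec:
    """One constitutive model class and its active parameter list."""

    id: str
    active_params: tuple[str, ...]

    @property
    def dim(self) -> int:
        return len(self.active_params)


def hypothesis(hid) -> HypothesisSpec:
    """Resolve a hypothesis id (``"H1"``..``"H5"``) to its spec."""
    if isinstance(hid, HypothesisSpec):
        return hid
    try:
        return HypothesisSpec(hid, HYPOTHESES[hid])
    except KeyError:
        valid = ", ".join(HYPOTHESES)
        raise ValueError(f"unknown hypothesis {hid!r}; valid ids: {valid}") from None


@dataclass(frozen=True)
class LoadProtocol:
    """Triangular stress-controlled protocol: 0 -> sigma_max -> 0 over 2T.

    Parameters
    ----------
    sigma_max : float
        Peak stress (Pa), reached at t = T.
    half_duration : float
        T (s); the full test lasts 2T.
    dt_sample : float
        Sampling interval of the strain sensor (s).
    """

    sigma_max: float = 1.0e6
    half_duration: float = 1.0
    dt_sample: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_max <= 0 or self.half_duration <= 0 or self.dt_sample <= 0:
            raise ValueError("protocol fields must be strictly positive")
        if self.dt_sample > 2.0 * self.half_duration + 1e-12:
            raise ValueError("dt_sample must not exceed the test duration 2T")

    @property
    def duration(self) -> float:
        return 2.0 * self.half_duration

    def sample_times(self) -> np.ndarray:
        return self.dt_sample * np.arange(count_samples(self))


def count_samples(p: LoadProtocol) -> int:
    """Number of sampling instants, both endpoints included."""
    # small epsilon guards the floor against float division artefacts
    return int(math.floor(p.duration / p.dt_sample + 1e-9)) + 1


def stress_at(t, p: LoadProtocol):
    """Applied stress at time(s) ``t`` of the triangular protocol."""
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > p.duration + 1e-9):
        raise ValueError(f"time outside [0, {p.duration}]")
    T = p.half_duration
    out = p.sigma_max * np.where(t <= T, t / T, 2.0 - t / T)
    out = np.clip(out, 0.0, p.sigma_max)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MaterialParams:
    """Material constants; inactive parameters are ``None``, never zero."""

    mu: float
    eta: Optional[float] = None
    A: Optional[float] = None
    D: Optional[float] = None

    def require(self, names: tuple[str, ...]) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"parameters {missing} required but not set")


@dataclass
class StrainSeries:
    """Sampled output of a forward simulation (strains dimensionless)."""

    times: np.ndarray
    stresses: np.ndarray
    strains: np.ndarray
    elastic: np.ndarray
    viscous: np.ndarray


def elastic_strain(sigma, mu, A=0.0, D=0.0, tol=1e-13, max_iter=80):
    """Elastic strain of the nonlinear spring: root of mu*e + A*e^2 + D*e^3 = sigma.

    Returns the branch continuous in (A, D) with the linear solution sigma/mu,
    found by a safeguarded Newton iteration started at sigma/mu.  For the
    admissible region (mu > 0, A, D >= 0, sigma >= 0) the polynomial is
    strictly increasing on e >= 0, so that branch is the unique nonnegative
    root and Newton from the (over-estimating) linear start converges
    monotonically; the bracket [0, sigma/mu] is enforced as a safeguard.
    All arguments broadcast.
    """
    sigma = np.asarray(sigma, dtype=float)
    mu = np.asarray(mu, dtype=float)
    A = np.asarray(0.0 if A is None else A, dtype=float)
    D = np.asarray(0.0 if D is None else D, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    if np.any(sigma < 0) or np.any(A < 0) or np.any(D < 0):
        raise ValueError("sigma, A and D must be nonnegative")

    shape = np.broadcast(sigma, mu, A, D).shape
    e = np.broadcast_to(sigma / mu, shape).copy()  # linear start = upper bound
    for _ in range(max_iter):
        f = mu * e + A * e**2 + D * e**3 - sigma
        fp = mu + 2.0 * A * e + 3.0 * D * e**2
        step = f / fp
        e -= step
        if float(np.max(np.abs(step))) <= tol * max(1.0, float(np.max(np.abs(e)))):
            break
    # From the overestimating start Newton descends monotonically on this
    # increasing convex branch; a safeguard clip keeps rounding on it.
    out = np.clip(e, 0.0, None)
    return float(out) if out.ndim == 0 else out


def _viscous_kernel(p: LoadProtocol, dt_int: float, aging: bool) -> np.ndarray:
    """Trapezoidal cumulative integral, at the sample times, of the dashpot rate
    numerator: integral of sigma(t) dt (Maxwell), or of sigma(t)/(3 t) dt (aging
    dashpot, with the t -> 0 ramp limit sigma_max/(3 T) as integrand at zero).

    Dividing the returned kernel by eta (or by mu for the aging law) gives the
    viscous strain — valid because the rate never depends on the strain state.
    """
    n_fine = max(int(math.ceil(p.duration / dt_int)), 1)
    t = np.linspace(0.0, p.duration, n_fine + 1)
    sig = stress_at(t, p)
    if aging:
        g = np.empty_like(sig)
        g[1:] = sig[1:] / (3.0 * t[1:])
        g[0] = p.sigma_max / (3.0 * p.half_duration)
    else:
        g = sig
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(t))))
    return np.interp(p.sample_times(), t, cum)


def forward_batch(
    h,
    params: dict[str, np.ndarray],
    p: LoadProtocol,
    dt_int: float = 1e-3,
) -> np.ndarray:
    """Strain curves for a batch of parameter sets under one hypothesis.

    ``params`` maps each active parameter name to an array of shape (N,);
    returns strains of shape (N, n_samples).  This is the vectorized path the
    Monte-Carlo loops use; ``simulate`` wraps it for a single parameter set.
    """
    h = hypothesis(h)
    mu = np.atleast_1d(np.asarray(params["mu"], dtype=float))
    sig = stress_at(p.sample_times(), p)

    A = params.get("A")
    D = params.get("D")
    if A is None and D is None:
        eps_e = sig[None, :] / mu[:, None]
    else:
        A = np.atleast_1d(np.asarray(A, dtype=float))[:, None] if A is not None else 0.0
        D = np.atleast_1d(np.asarray(D, dtype=float))[:, None] if D is not None else 0.0
        # the triangular protocol revisits stress levels on unloading; solve
        # the nonlinear spring only once per distinct stress
        sig_u, inverse = np.unique(sig, return_inverse=True)
        eps_e = elastic_strain(sig_u[None, :], mu[:, None], A, D)[:, inverse]

    if h.id == "H5":
        eps_v = _viscous_kernel(p, dt_int, aging=True)[None, :] / mu[:, None]
    elif "eta" in h.active_params:
        eta = np.atleast_1d(np.asarray(params["eta"], dtype=float))
        eps_v = _viscous_kernel(p, dt_int, aging=False)[None, :] / eta[:, None]
    else:
        eps_v = np.zeros_like(eps_e)
    return eps_e + eps_v


def simulate(
    h,
    m: MaterialParams,
    p: LoadProtocol,
    dt_int: float = 1e-3,
) -> StrainSeries:
    """Forward-simulate one parameter set; returns the sampled strain series
    with its elastic/viscous decomposition."""
    h = hypothesis(h)
    m.require(h.active_params)
    params = {name: np.array([getattr(m, name)]) for name in h.active_params}
    sig = stress_at(p.sample_times(), p)
    eps_e = elastic_strain(
        sig,
        m.mu,
        getattr(m, "A", None) if "A" in h.active_params else 0.0,
        getattr(m, "D", None) if "D" in h.active_params else 0.0,
    )
    total = forward_batch(h, params, p, dt_int)[0]
    return StrainSeries(
        times=p.sample_times(),
        stresses=sig,
        strains=total,
        elastic=np.asarray(eps_e),
        viscous=total - np.asarray(eps_e),
    )
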