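"""Information-density algebra and its Gaussian particularization.

An *information density* f(x) is an unnormalized nonnegative plausibility
measure over a labeled variable space: zero means the value is impossible,
larger means more plausible, and no total-mass axiom is imposed.  Two
independent sources of information about the same variables combine by the
logical operators

    AND:  (f1 and f2)(x) = f1(x) * f2(x)
    OR:   (f1 or f2)(x)  = f1(x) + f2(x)

which reduce to the Boolean truth tables on {0, 1}-valued densities.  The
constant density 1 is the noninformative state and the AND identity.

With Gaussian observation uncertainty (covariance Co) and Gaussian model
error (covariance Cm), conjoining the experimental and model densities and
marginalizing over the observation space collapses to a single Gaussian form
in the residuals with covariance Co + Cm, i.e. an unnormalized posterior
weight exp(-J) with the quadratic misfit

    J(M) = 1/2 * r^T (Co + Cm)^{-1} r,      r_i = eps_i^sim(M) - eps_i^obs.

Evidences (unit-cube integrals of exp(-J)) are estimated by plain Monte-Carlo
averaging; the accumulation is done in the log domain so that large misfits
never underflow to a spuriously zero evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "InformationDensity",
    "CovarianceModel",
    "and_combine",
    "or_combine",
    "misfit",
    "misfit_batch",
    "posterior_weight",
    "mc_integral",
    "evidence_from_misfits",
    "log_evidence_from_misfits",
    "normalize",
    "AllModelsFalsified",
]


class AllModelsFalsified(RuntimeError):
    """Raised when every candidate explanation has zero information density."""


@dataclass(frozen=True)
class InformationDensity:
    """An unnormalized plausibility measure over named variables."""

    variables: tuple[str, ...]
    fn: Callable[..., float]

    def __call__(self, *args):
        v = self.fn(*args)
        if np.any(np.asarray(v) < 0):
            raise ValueError("information density must be nonnegative")
        return v


def _check_same_space(f1: InformationDensity, f2: InformationDensity) -> None:
    if f1.variables != f2.variables:
        raise ValueError(
            f"cannot combine densities over {f1.variables} and {f2.variables}"
        )


def and_combine(f1: InformationDensity, f2: InformationDensity) -> InformationDensity:
    """Conjunction: pointwise product (both sources simultaneously plausible)."""
    _check_same_space(f1, f2)
    return InformationDensity(f1.variables, lambda *x: f1(*x) * f2(*x))


def or_combine(f1: InformationDensity, f2: InformationDensity) -> InformationDensity:
    """Disjunction: pointwise sum (either source plausible)."""
    _check_same_space(f1, f2)
    return InformationDensity(f1.variables, lambda *x: f1(*x) + f2(*x))


@dataclass
class CovarianceModel:
    """Observation covariance Co plus optional model-error covariance Cm.

    Either may be a diagonal (1-D array of per-sample variances) or a full
    symmetric matrix; the combined covariance Co + Cm must be positive
    definite.  Cm defaults to zero: numerical model error is usually
    negligible next to measurement noise.
    """

    obs: np.ndarray
    model: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.obs = np.asarray(self.obs, dtype=float)
        if self.model is not None:
            self.model = np.asarray(self.model, dtype=float)
            if self.model.shape != self.obs.shape:
                raise ValueError("Co and Cm must have the same shape")

    @property
    def is_diagonal(self) -> bool:
        return self.obs.ndim == 1

    def combined(self) -> np.ndarray:
        c = self.obs if self.model is None else self.obs + self.model
        if self.is_diagonal:
            if np.any(c <= 0):
                raise ValueError("combined covariance must be positive definite")
        return c


def misfit_batch(sims: np.ndarray, obs_strains: np.ndarray, cov: CovarianceModel) -> np.ndarray:
    """Quadratic misfit J for a batch of simulated curves, shape (N, n) -> (N,)."""
    sims = np.atleast_2d(np.asarray(sims, dtype=float))
    obs_strains = np.asarray(obs_strains, dtype=float)
    if sims.shape[1] != obs_strains.shape[0]:
        raise ValueError(
            f"simulated series has {sims.shape[1]} samples, observations have "
            f"{obs_strains.shape[0]}"
        )
    r = sims - obs_strains[None, :]
    c = cov.combined()
    if cov.is_diagonal:
        if c.shape[0] != obs_strains.shape[0]:
            raise ValueError("covariance size does not match observations")
        return 0.5 * np.sum(r * r / c[None, :], axis=1)
    try:
        factor = cho_factor(c)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises ValueError
        raise ValueError("combined covariance is singular") from exc
    return 0.5 * np.sum(r * cho_solve(factor, r.T).T, axis=1)


def misfit(sim, obs_strains, cov: CovarianceModel) -> float:
    """Misfit of one simulated series against the observations.

    ``sim`` may be a strain array or any object with a ``strains`` attribute.
    """
    strains = getattr(sim, "strains", sim)
    return float(misfit_batch(np.asarray(strains)[None, :], obs_strains, cov)[0])


def posterior_weight(J):
    """Unnormalized posterior weight exp(-J); J = +inf maps to exactly 0."""
    J = np.asarray(J, dtype=float)
    if np.any(J < 0):
        raise ValueError("misfit must be nonnegative")
    with np.errstate(under="ignore"):
        w = np.exp(-J)
    return float(w) if w.ndim == 0 else w


def mc_integral(values) -> tuple[float, float]:
    """Plain Monte-Carlo estimate of a unit-cube integral.

    ``values`` are the integrand evaluations at uniform unit-cube samples.
    Returns (mean, standard error of the mean).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot integrate an empty sample")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0


def log_evidence_from_misfits(J: np.ndarray) -> tuple[float, float]:
    """Log-evidence log(mean(exp(-J))) over unit-cube samples, with the
    relative standard error of the evidence.

    Accumulated as -J_min + log(mean(exp(-(J - J_min)))) so that uniformly
    large misfits shift rather than underflow; +inf misfits (falsified
    forward evaluations) contribute exactly zero weight.  Returns
    (log I, se(I)/I); an entirely falsified sample gives (-inf, 0).
    """
    J = np.asarray(J, dtype=float)
    if J.size == 0:
        raise ValueError("cannot estimate evidence from an empty sample")
    jmin = np.min(J)
    if not np.isfinite(jmin):
        return -np.inf, 0.0
    with np.errstate(under="ignore"):
        u = np.exp(-(J - jmin))
    mean, se = mc_integral(u)
    return float(-jmin + np.log(mean)), se / mean


def evidence_from_misfits(J: np.ndarray) -> tuple[float, float]:
    """Evidence I = mean(exp(-J)) with its standard error (linear scale).

    Underflows to zero for log-evidences below roughly -745; use
    ``log_evidence_from_misfits`` when ratios of astronomically small
    evidences are needed.
    """
    logI, rel_se = log_evidence_from_misfits(J)
    if logI == -np.inf:
        return 0.0, 0.0
    with np.errstate(under="ignore"):
        I = float(np.exp(logI))
    return I, I * rel_se


def normalize(I: float) -> float:
    """Normalization constant 1/I turning exp(-J) into a unit-mass density."""
    if I < 0:
        raise ValueError("evidence must be nonnegative")
    if I == 0.0:
        raise AllModelsFalsified(
            "evidence is zero: the model is impossible under the observations"
        )
    return 1.0 / I
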