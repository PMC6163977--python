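"""Jeffreys logarithmic parametrization and unit-cube sampling.

Positive material parameters such as stiffness and viscosity are *Jeffreys
type*: their reciprocals (compliance, fluidity) are equally natural, so a
noninformative state of knowledge must be invariant under inversion.  The
standard device is a logarithmic change of variable.  Each physical parameter
``m`` with admissible range ``[lower, upper]`` (both strictly positive) is
mapped to a normalized coordinate

    u = ln(m / lower) / ln(upper / lower)        in [0, 1]

so that a constant density on the unit cube is log-uniform in physical space
and invariant under ``m -> 1/m`` (with reciprocal bounds).  All Monte-Carlo
integration in this package happens on the unit cube, which gives every
hypothesis's noninformative prior unit mass regardless of its dimensionality —
the mechanism by which model complexity is automatically penalized when
evidences are compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParameterBounds",
    "to_normalized",
    "from_normalized",
    "sample_unit_cube",
    "default_bounds",
]


@dataclass(frozen=True)
class ParameterBounds:
    """Admissible range of one positive (Jeffreys-type) physical parameter.

    Parameters
    ----------
    name : str
        Parameter identifier (``"mu"``, ``"eta"``, ``"A"``, ``"D"``).
    lower, upper : float
        Strictly positive range limits, in the parameter's SI units.
    units : str
        Unit string for reporting only.
    """

    name: str
    lower: float
    upper: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper):
            raise ValueError(
                f"bounds for {self.name!r} must satisfy 0 < lower < upper, "
                f"got [{self.lower}, {self.upper}]"
            )

    @property
    def log_span(self) -> float:
        return math.log(self.upper / self.lower)

    def contains(self, m) -> bool:
        return bool(np.all((m >= self.lower) & (m <= self.upper)))


def to_normalized(m, bounds: ParameterBounds):
    """Map physical value(s) ``m`` to the normalized coordinate in [0, 1].

    Raises ``ValueError`` if any value lies outside the bounds (which also
    catches non-positive values, since ``lower > 0``).
    """
    m = np.asarray(m, dtype=float)
    if np.any(m < bounds.lower) or np.any(m > bounds.upper):
        raise ValueError(
            f"value outside bounds [{bounds.lower}, {bounds.upper}] "
            f"for parameter {bounds.name!r}"
        )
    out = np.log(m / bounds.lower) / bounds.log_span
    return float(out) if out.ndim == 0 else out


def from_normalized(u, bounds: ParameterBounds):
    """Inverse map: normalized coordinate(s) in [0, 1] to physical value(s)."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError(f"normalized coordinate outside [0, 1] for {bounds.name!r}")
    out = bounds.lower * np.exp(u * bounds.log_span)
    return float(out) if out.ndim == 0 else out


def sample_unit_cube(n: int, d: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. uniform points on [0, 1]^d, reproducibly.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a
    ``numpy.random.Generator``.  The same seed always yields the same points.
    """
    if n < 0 or d < 1:
        raise ValueError("need n >= 0 and d >= 1")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    return rng.random((n, d))


# One decade each way around the generating truth of the worked example
# (mu = 1 MPa, eta = 10 MPa*s, A = 15 kPa); D shares A's range since both are
# higher-order corrections of the same elastic law.  All values SI.
_DEFAULTS = {
    "mu": (1.0e5, 1.0e7, "Pa"),
    "eta": (1.0e6, 1.0e8, "Pa·s"),
    "A": (1.5e3, 1.5e5, "Pa"),
    "D": (1.5e3, 1.5e5, "Pa"),
}


def default_bounds() -> dict[str, ParameterBounds]:
    """Default parameter ranges: log-symmetric decades around the example truth."""
    return {
        name: ParameterBounds(name, lo, hi, units)
        for name, (lo, hi, units) in _DEFAULTS.items()
    }
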