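"""Synthetic tensile-test data: forward-simulate a truth, add Gaussian noise.

The worked example interrogates a soft-tissue-like sample with a triangular
stress protocol (0 -> 1 MPa -> 0 over 2 s, sampled every 0.1 s) and generates
the "experimental" strains from model H1 with mu = 1 MPa, eta = 10 MPa*s,
A = 15 kPa, corrupted by i.i.d. Gaussian measurement noise.  Three noise
parametrizations are supported:

``stress``
    Standard deviation stated as an equivalent stress (Pa) and mapped to a
    strain standard deviation through the linear compliance of the truth,
    ``sd_eps = sd_sigma / mu``.  This is the default, matching a displacement
    sensor whose error is quoted as 10 kPa of equivalent stress.
``relative``
    ``sd_i = magnitude * |eps_i|`` per datum, with an absolute floor so the
    zero-strain endpoints keep a positive variance.
``absolute``
    Constant strain standard deviation.

The per-sample variances actually used are recorded on the observation set
and feed the observation covariance Co of the inference (self-consistent
noise model).  Every generated set carries its seed and generating
configuration, so it can be regenerated bit-identically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .models import (
    HypothesisSpec,
    LoadProtocol,
    MaterialParams,
    hypothesis,
    simulate,
)

__all__ = [
    "NoiseSpec",
    "ObservationSet",
    "generate",
    "read_observations",
    "write_observations",
    "DEFAULT_TRUTH",
    "DEFAULT_PROTOCOL",
    "DEFAULT_NOISE",
]

_MODES = ("stress", "relative", "absolute")

#: Generating truth of the worked example (SI units).
DEFAULT_TRUTH = MaterialParams(mu=1.0e6, eta=1.0e7, A=1.5e4)
#: 2T = 2 s triangular test to 1 MPa, sampled at 10 Hz (21 instants).
DEFAULT_PROTOCOL = LoadProtocol(sigma_max=1.0e6, half_duration=1.0, dt_sample=0.1)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian measurement-noise model for the strain sensor.

    ``magnitude`` is in Pa for mode ``"stress"``, a fraction for
    ``"relative"``, and a strain standard deviation for ``"absolute"``.
    ``floor`` is an absolute strain-sd lower bound applied in every mode.
    """

    mode: str = "stress"
    magnitude: float = 1.0e4
    floor: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"noise mode must be one of {_MODES}")
        if self.magnitude <= 0 or self.floor <= 0:
            raise ValueError("noise magnitude and floor must be positive")

    def sd(self, noiseless: np.ndarray, mu_ref: Optional[float] = None) -> np.ndarray:
        """Per-sample strain standard deviations for a noiseless series."""
        noiseless = np.asarray(noiseless, dtype=float)
        if self.mode == "relative":
            sd = self.magnitude * np.abs(noiseless)
        elif self.mode == "absolute":
            sd = np.full_like(noiseless, self.magnitude)
        else:  # stress-equivalent
            if mu_ref is None or mu_ref <= 0:
                raise ValueError(
                    "stress-equivalent noise needs a positive reference modulus"
                )
            sd = np.full_like(noiseless, self.magnitude / mu_ref)
        return np.maximum(sd, self.floor)


DEFAULT_NOISE = NoiseSpec()


@dataclass
class ObservationSet:
    """Measured (or synthesized) strain record with its noise description."""

    times: np.ndarray
    stresses: np.ndarray
    strains: np.ndarray
    variances: np.ndarray
    noise: Optional[NoiseSpec] = None
    seed: Optional[int] = None
    provenance: dict = field(default_factory=lambda: {"origin": "external"})

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.stresses = np.asarray(self.stresses, dtype=float)
        self.strains = np.asarray(self.strains, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        n = self.times.shape[0]
        if not (self.stresses.shape[0] == self.strains.shape[0] == self.variances.shape[0] == n):
            raise ValueError("times, stresses, strains and variances must share length")
        if np.any(self.variances <= 0):
            raise ValueError("observation variances must be strictly positive")

    @property
    def n(self) -> int:
        return self.times.shape[0]


def generate(
    h,
    truth: MaterialParams,
    protocol: LoadProtocol,
    noise: NoiseSpec = DEFAULT_NOISE,
    seed: int = 0,
    dt_int: float = 1e-3,
) -> ObservationSet:
    """Synthesize one noisy experiment from a known truth.

    The same (hypothesis, truth, protocol, noise, seed) always yields the
    same data.
    """
    h = hypothesis(h)
    clean = simulate(h, truth, protocol, dt_int=dt_int)
    sd = noise.sd(clean.strains, mu_ref=truth.mu)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    observed = clean.strains + sd * rng.standard_normal(clean.strains.shape)
    return ObservationSet(
        times=clean.times,
        stresses=clean.stresses,
        strains=observed,
        variances=sd**2,
        noise=noise,
        seed=int(seed),
        provenance={
            "origin": "synthetic",
            "hypothesis": h.id,
            "truth": {p: getattr(truth, p) for p in h.active_params},
            "protocol": {
                "sigma_max": protocol.sigma_max,
                "half_duration": protocol.half_duration,
                "dt_sample": protocol.dt_sample,
            },
            "noise": {"mode": noise.mode, "magnitude": noise.magnitude, "floor": noise.floor},
            "seed": int(seed),
        },
    )


_COLUMNS = ("time_s", "stress_Pa", "strain")


def write_observations(obs: ObservationSet, path) -> None:
    """Write an observation set as delimited text (CSV, 17 significant digits)."""
    frame = pd.DataFrame(
        {
            "time_s": obs.times,
            "stress_Pa": obs.stresses,
            "strain": obs.strains,
            "strain_var": obs.variances,
        }
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_observations(path, variance: Optional[float] = None) -> ObservationSet:
    """Read a delimited observation file.

    The file must carry columns ``time_s, stress_Pa, strain``; a
    ``strain_var`` column is optional and, when absent, a constant
    ``variance`` must be supplied by the caller.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in _COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    times = frame["time_s"].to_numpy(dtype=float)
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 2  # +1 header, +1 next data row
        raise ValueError(f"{path}: times not strictly increasing at line {row + 1}")
    if "strain_var" in frame.columns:
        variances = frame["strain_var"].to_numpy(dtype=float)
    elif variance is not None:
        variances = np.full(times.shape, float(variance))
    else:
        raise ValueError(
            f"{path}: no strain_var column and no fallback variance supplied"
        )
    return ObservationSet(
        times=times,
        stresses=frame["stress_Pa"].to_numpy(dtype=float),
        strains=frame["strain"].to_numpy(dtype=float),
        variances=variances,
        provenance={"origin": "external", "path": str(path)},
    )
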