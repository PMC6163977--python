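"""Posterior reconstruction of material parameters under a fixed model class.

The unnormalized posterior over the active parameters M of a hypothesis is
exp(-J(M)) with J the Gaussian misfit of the forward-simulated strain curve
against the observations.  It is explored by plain Monte Carlo: N points
uniform on the normalized unit cube (log-uniform in physical space), each
mapped to physical parameters, forward-simulated, and scored.  From the
weighted sample the package reports 1-D marginals (weighted histograms with
a light moving-average smooth), the mode / weighted median / weighted
standard deviation per parameter, and 2-D plausibility slices with the
remaining parameters clamped at their most probable values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .information import (
    CovarianceModel,
    evidence_from_misfits,
    log_evidence_from_misfits,
    misfit_batch,
)
from .models import PARAM_ORDER, HypothesisSpec, LoadProtocol, forward_batch, hypothesis
from .parameters import ParameterBounds, default_bounds, from_normalized, sample_unit_cube
from .synthetic import ObservationSet

__all__ = [
    "PosteriorSamples",
    "MarginalCurve",
    "reconstruct",
    "marginal_1d",
    "joint_slice_2d",
    "point_estimate",
    "protocol_from_observations",
]

DEFAULT_N = 2**16
DEFAULT_BINS = 64


def protocol_from_observations(obs: ObservationSet) -> LoadProtocol:
    """Recover the triangular protocol implied by an observation record."""
    prov = obs.provenance.get("protocol") if obs.provenance else None
    if prov:
        return LoadProtocol(prov["sigma_max"], prov["half_duration"], prov["dt_sample"])
    peak = int(np.argmax(obs.stresses))
    dt = float(np.median(np.diff(obs.times)))
    return LoadProtocol(float(obs.stresses[peak]), float(obs.times[peak]), dt)


@dataclass
class PosteriorSamples:
    """Weighted Monte-Carlo sample of the posterior of one hypothesis."""

    hypothesis: HypothesisSpec
    bounds: dict[str, ParameterBounds]
    points: np.ndarray        # (N, d) normalized coordinates
    physical: np.ndarray      # (N, d) physical values
    misfits: np.ndarray       # (N,)
    seed: object
    protocol: LoadProtocol

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def weights(self) -> np.ndarray:
        with np.errstate(under="ignore"):
            return np.exp(-self.misfits)

    def evidence(self) -> tuple[float, float]:
        """Monte-Carlo evidence I = mean exp(-J) over the unit cube, with se."""
        return evidence_from_misfits(self.misfits)

    def log_evidence(self) -> tuple[float, float]:
        """Log-evidence with the relative standard error (underflow-safe)."""
        return log_evidence_from_misfits(self.misfits)

    def column(self, param: str) -> int:
        try:
            return self.hypothesis.active_params.index(param)
        except ValueError:
            raise ValueError(
                f"parameter {param!r} not active in {self.hypothesis.id}"
            ) from None


def _covariance(obs: ObservationSet, cov: Optional[CovarianceModel]) -> CovarianceModel:
    return cov if cov is not None else CovarianceModel(obs.variances)


def reconstruct(
    h,
    obs: ObservationSet,
    bounds: Optional[dict[str, ParameterBounds]] = None,
    n_samples: int = DEFAULT_N,
    seed=0,
    cov: Optional[CovarianceModel] = None,
    dt_int: float = 1e-3,
) -> PosteriorSamples:
    """Sample the posterior of hypothesis ``h`` given the observations.

    Deterministic for a fixed seed.  Forward-model failures become infinite
    misfits (zero weight) rather than aborting the run.
    """
    h = hypothesis(h)
    bounds = bounds if bounds is not None else default_bounds()
    protocol = protocol_from_observations(obs)
    # Common random numbers: one 4-column base sample per seed, from which a
    # hypothesis takes the columns of its active parameters.  Reconstructions
    # of different model classes at the same seed therefore share coordinates
    # in the parameters they have in common, so evidence ratios (the Occam
    # comparisons) carry far less Monte-Carlo noise than independent streams.
    base = sample_unit_cube(int(n_samples), len(PARAM_ORDER), seed)
    pts = base[:, [PARAM_ORDER.index(name) for name in h.active_params]]
    phys = np.empty_like(pts)
    for j, name in enumerate(h.active_params):
        phys[:, j] = from_normalized(pts[:, j], bounds[name])
    params = {name: phys[:, j] for j, name in enumerate(h.active_params)}
    try:
        sims = forward_batch(h, params, protocol, dt_int=dt_int)
        J = misfit_batch(sims, obs.strains, _covariance(obs, cov))
    except FloatingPointError:  # pragma: no cover - defensive
        J = np.full(pts.shape[0], np.inf)
    J = np.where(np.isfinite(J), J, np.inf)
    return PosteriorSamples(h, bounds, pts, phys, J, seed, protocol)


@dataclass
class MarginalCurve:
    """1-D marginal density of one parameter (unit area in normalized coords)."""

    param: str
    bounds: ParameterBounds
    edges: np.ndarray          # normalized bin edges, nbins + 1
    centers_physical: np.ndarray
    density: np.ndarray        # nonnegative, integrates to 1 over [0, 1]
    mode: float                # physical value, refined smoothed-histogram peak
    mode_bin: float            # physical value of the peak bin centre
    mode_raw: float            # physical value of the maximum-weight sample
    median: float              # weighted 50% quantile, physical
    std: float                 # weighted standard deviation, physical


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    return float(np.interp(q, cdf, v))


def _smooth3(y: np.ndarray) -> np.ndarray:
    padded = np.concatenate(([y[0]], y, [y[-1]]))
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _peak_position(density: np.ndarray) -> float:
    """Normalized coordinate of the histogram peak.

    Argmax bin (ties -> lowest) refined by the vertex of the parabola through
    the peak bin and its neighbours, which removes the half-bin quantization
    that would otherwise dominate for posteriors narrower than one bin.
    """
    nbins = density.shape[0]
    k = int(np.argmax(density))
    delta = 0.0
    if 0 < k < nbins - 1:
        curv = density[k - 1] - 2.0 * density[k] + density[k + 1]
        if curv < 0.0:
            delta = 0.5 * (density[k - 1] - density[k + 1]) / curv
            delta = float(np.clip(delta, -0.5, 0.5))
    return min(max((k + 0.5 + delta) / nbins, 0.0), 1.0)


def marginal_1d(
    ps: PosteriorSamples,
    param: str,
    nbins: int = DEFAULT_BINS,
    smooth: bool = True,
) -> MarginalCurve:
    """Weighted-histogram marginal of one active parameter.

    The histogram lives on the normalized coordinate (64 bins by default) and
    is normalized to unit area there; the reported mode is the peak of the
    (3-bin moving-average) smoothed histogram, refined to sub-bin accuracy by
    parabolic interpolation and mapped back to physical units (the raw peak
    bin centre is kept as ``mode_bin``).  Median and standard deviation are
    weighted statistics of the physical sample values.
    """
    j = ps.column(param)
    w = ps.weights
    total = w.sum()
    if total <= 0.0:
        raise ValueError(
            f"all posterior weights are zero: {ps.hypothesis.id} is falsified"
        )
    coords = ps.points[:, j]
    hist, edges = np.histogram(coords, bins=nbins, range=(0.0, 1.0), weights=w)
    density = hist / total * nbins  # unit area over [0, 1]
    peaked = _smooth3(density) if smooth else density
    k = int(np.argmax(peaked))  # ties: lowest bin
    centers = 0.5 * (edges[:-1] + edges[1:])
    b = ps.bounds[param]
    mode = from_normalized(_peak_position(peaked), b)
    mode_bin = from_normalized(centers[k], b)
    phys = ps.physical[:, j]
    mean = float(np.sum(w * phys) / total)
    var = float(np.sum(w * (phys - mean) ** 2) / total)
    return MarginalCurve(
        param=param,
        bounds=b,
        edges=edges,
        centers_physical=np.asarray(from_normalized(centers, b)),
        density=density,
        mode=float(mode),
        mode_bin=float(mode_bin),
        mode_raw=float(phys[int(np.argmax(w))]),
        median=_weighted_quantile(phys, w, 0.5),
        std=np.sqrt(var),
    )


def point_estimate(ps: PosteriorSamples, nbins: int = DEFAULT_BINS) -> dict:
    """Most-probable parameters: joint mode (maximum-weight sample, ties broken
    by lowest sample index) plus per-parameter marginal modes."""
    if ps.n == 0:
        raise ValueError("empty posterior sample")
    k = int(np.argmax(ps.weights))
    joint = {
        name: float(ps.physical[k, j])
        for j, name in enumerate(ps.hypothesis.active_params)
    }
    marg = {
        name: marginal_1d(ps, name, nbins=nbins).mode
        for name in ps.hypothesis.active_params
    }
    return {"joint_mode": joint, "marginal_modes": marg, "sample_index": k}


def joint_slice_2d(
    h,
    obs: ObservationSet,
    params: tuple[str, str],
    fixed: Optional[dict[str, float]] = None,
    bounds: Optional[dict[str, ParameterBounds]] = None,
    resolution: int = 64,
    cov: Optional[CovarianceModel] = None,
    dt_int: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plausibility slice exp(-J) over a regular lattice of two parameters.

    The other active parameters are clamped at ``fixed`` (normalized
    coordinates, typically the marginal modes).  Returns the two physical
    axes and the (resolution x resolution) unnormalized weight grid, indexed
    [i, j] = (params[0] axis i, params[1] axis j).
    """
    h = hypothesis(h)
    if len(params) != 2 or params[0] == params[1]:
        raise ValueError("exactly two distinct parameters are required")
    if h.dim < 2:
        raise ValueError(f"{h.id} has fewer than two free parameters")
    for p in params:
        if p not in h.active_params:
            raise ValueError(f"parameter {p!r} not active in {h.id}")
    others = [p for p in h.active_params if p not in params]
    fixed = dict(fixed or {})
    missing = [p for p in others if p not in fixed]
    if missing:
        raise ValueError(f"fixed normalized values required for {missing}")
    bounds = bounds if bounds is not None else default_bounds()
    protocol = protocol_from_observations(obs)

    axis = np.linspace(0.0, 1.0, resolution)
    g1, g2 = np.meshgrid(axis, axis, indexing="ij")
    batch: dict[str, np.ndarray] = {}
    for name in h.active_params:
        if name == params[0]:
            u = g1.ravel()
        elif name == params[1]:
            u = g2.ravel()
        else:
            u = np.full(resolution * resolution, float(fixed[name]))
        batch[name] = np.asarray(from_normalized(u, bounds[name]))
    sims = forward_batch(h, batch, protocol, dt_int=dt_int)
    J = misfit_batch(sims, obs.strains, _covariance(obs, cov))
    with np.errstate(under="ignore"):
        grid = np.exp(-J).reshape(resolution, resolution)
    ax1 = np.asarray(from_normalized(axis, bounds[params[0]]))
    ax2 = np.asarray(from_normalized(axis, bounds[params[1]]))
    return ax1, ax2, grid
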