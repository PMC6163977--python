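"""Model-class selection: evidence, plausibility ranking, robust mixtures.

The plausibility of a model class Hk given the data is proportional to its
evidence — the integral of the posterior weight exp(-J) over Hk's normalized
parameter cube.  Because every cube has unit noninformative mass, evidences of
hypotheses with different numbers of parameters are directly comparable, and
extra dimensions that do not buy misfit reduction dilute the integral: an
automatic Occam penalty.  Normalizing the (optionally prior-weighted)
evidences over the candidate set gives the ranking

    p(Hk) = f_o(Hk) I_k / sum_j f_o(Hj) I_j.

Robust reconstruction mixes the per-hypothesis marginal densities of a shared
parameter with these plausibilities; hypotheses in which the parameter is
inactive contribute their noninformative constant density, so they flatten
rather than shift the mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .information import AllModelsFalsified, CovarianceModel
from .models import HYPOTHESES, HypothesisSpec, hypothesis
from .parameters import ParameterBounds, default_bounds, from_normalized
from .reconstruction import DEFAULT_BINS, DEFAULT_N, PosteriorSamples, marginal_1d, reconstruct
from .synthetic import ObservationSet

__all__ = [
    "HypothesisRanking",
    "evidence",
    "rank",
    "rank_from_evidence",
    "robust_reconstruct",
]



def evidence(
    h,
    obs: ObservationSet,
    bounds: Optional[dict[str, ParameterBounds]] = None,
    n_samples: int = DEFAULT_N,
    seed=0,
    cov: Optional[CovarianceModel] = None,
    samples: Optional[PosteriorSamples] = None,
) -> tuple[float, float]:
    """Evidence I_k of one hypothesis with its Monte-Carlo standard error.

    Reuses an existing posterior sample when provided.
    """
    if samples is None:
        samples = reconstruct(h, obs, bounds=bounds, n_samples=n_samples, seed=seed, cov=cov)
    return samples.evidence()


@dataclass
class HypothesisRanking:
    """Evidences and normalized plausibilities of a candidate set."""

    ids: tuple[str, ...]
    evidences: np.ndarray
    std_errors: np.ndarray
    plausibilities: np.ndarray
    samples: Optional[dict[str, PosteriorSamples]] = None

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.plausibilities

    def best(self) -> str:
        return self.ids[int(np.argmax(self.plausibilities))]

    def table(self) -> list[dict]:
        return [
            {
                "hypothesis": hid,
                "evidence": float(self.evidences[i]),
                "std_error": float(self.std_errors[i]),
                "plausibility": float(self.plausibilities[i]),
                "percent": float(self.percentages[i]),
            }
            for i, hid in enumerate(self.ids)
        ]


def rank_from_evidence(
    evidences: Sequence[float],
    priors: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Normalize (prior-weighted) evidences into plausibilities summing to 1."""
    I = np.asarray(evidences, dtype=float)
    if np.any(I < 0):
        raise ValueError("evidences must be nonnegative")
    w = I if priors is None else I * np.asarray(priors, dtype=float)
    total = w.sum()
    if total <= 0.0:
        raise AllModelsFalsified(
            "every candidate hypothesis has zero plausibility: all models falsified"
        )
    return w / total


def rank(
    hypotheses: Sequence,
    obs: ObservationSet,
    bounds: Optional[dict[str, ParameterBounds]] = None,
    n_samples: int = DEFAULT_N,
    seed: int = 0,
    priors: Optional[Sequence[float]] = None,
    cov: Optional[CovarianceModel] = None,
    keep_samples: bool = True,
) -> HypothesisRanking:
    """Rank candidate model classes by normalized evidence.

    Every hypothesis is reconstructed from the same seed, hence (by the
    common-random-numbers scheme of ``reconstruct``) on shared unit-cube
    coordinates in the parameters the candidates have in common.  Evidence
    ratios are then far less noisy than with independent streams, and the
    ranking is deterministic and insensitive to which other candidates are
    present.
    """
    specs = [hypothesis(h) for h in hypotheses]
    if len(specs) < 2:
        raise ValueError("ranking needs at least two candidate hypotheses")
    logI = np.empty(len(specs))
    rel_se = np.empty(len(specs))
    kept: dict[str, PosteriorSamples] = {}
    for i, h in enumerate(specs):
        ps = reconstruct(
            h, obs, bounds=bounds, n_samples=n_samples, seed=seed, cov=cov,
        )
        logI[i], rel_se[i] = ps.log_evidence()
        if keep_samples:
            kept[h.id] = ps
    # normalize in the log domain so that uniformly tiny evidences still rank
    if np.all(np.isinf(logI) & (logI < 0)):
        raise AllModelsFalsified(
            "every candidate hypothesis has zero plausibility: all models falsified"
        )
    with np.errstate(under="ignore"):
        I = np.exp(logI)
        shifted = np.exp(logI - np.max(logI[np.isfinite(logI)]))
    shifted[~np.isfinite(logI)] = 0.0
    p = rank_from_evidence(shifted, priors)
    se = I * rel_se
    return HypothesisRanking(
        ids=tuple(h.id for h in specs),
        evidences=I,
        std_errors=se,
        plausibilities=p,
        samples=kept or None,
    )


def robust_reconstruct(
    hypotheses: Sequence,
    obs: ObservationSet,
    params: Optional[Sequence[str]] = None,
    bounds: Optional[dict[str, ParameterBounds]] = None,
    n_samples: int = DEFAULT_N,
    seed: int = 0,
    priors: Optional[Sequence[float]] = None,
    nbins: int = DEFAULT_BINS,
) -> dict:
    """Plausibility-weighted mixture marginals across several model classes.

    For each requested parameter, hypotheses where it is active contribute
    their marginal density (on the shared normalized grid) weighted by p(Hk);
    hypotheses where it is inactive contribute the constant noninformative
    density 1, weighted.  A single-candidate call degenerates to the ordinary
    per-hypothesis marginal.  Returns, per parameter, the mixture density,
    grid, mode, and the component bookkeeping.
    """
    specs = [hypothesis(h) for h in hypotheses]
    bounds = bounds if bounds is not None else default_bounds()
    if len(specs) == 1:
        ps = reconstruct(specs[0], obs, bounds=bounds, n_samples=n_samples,
                         seed=seed)
        ranking = HypothesisRanking(
            (specs[0].id,), np.array([ps.evidence()[0]]),
            np.array([ps.evidence()[1]]), np.array([1.0]),
            {specs[0].id: ps},
        )
    else:
        ranking = rank(specs, obs, bounds=bounds, n_samples=n_samples,
                       seed=seed, priors=priors, keep_samples=True)

    if params is None:
        params = sorted({p for h in specs for p in h.active_params},
                        key=lambda p: ("mu", "eta", "A", "D").index(p))
    out: dict[str, dict] = {}
    centers = (np.arange(nbins) + 0.5) / nbins
    for name in params:
        active = [h.id for h in specs if name in h.active_params]
        if not active:
            raise ValueError(f"parameter {name!r} is active in no candidate hypothesis")
        mix = np.zeros(nbins)
        for i, hid in enumerate(ranking.ids):
            pk = ranking.plausibilities[i]
            if hid in active:
                curve = marginal_1d(ranking.samples[hid], name, nbins=nbins)
                mix += pk * curve.density
            else:
                mix += pk  # noninformative constant density 1 on [0, 1]
        k = int(np.argmax(mix))
        out[name] = {
            "grid_physical": np.asarray(from_normalized(centers, bounds[name])),
            "density": mix,
            "mode": float(from_normalized(centers[k], bounds[name])),
            "active_in": active,
            "ranking": ranking,
        }
    return out
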