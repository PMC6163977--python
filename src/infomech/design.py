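"""Interrogation-system design: information gain over a grid of test durations.

Before an experiment exists, each candidate design S (here: the half-duration
T of the triangular test, with the sampling interval held at its sensor value)
is assessed by synthesizing the experiment it would produce from a reference
truth and the declared noise model, and evaluating the marginal information
gain f(S): the evidence integral of exp(-J) over the model-parameter cube,
with the observation space already marginalized inside the Gaussian misfit.
Averaging the gain over several noise realizations per design reduces the
scan variance.  The gains are normalized to design plausibilities
p(S) = f(S) / sum f(S), from which the per-design entropy terms p log p and
the Shannon total -sum p log p follow (base configurable: bits, nats or
hartleys).

Two optimality criteria are exposed: the design maximizing the plausibility
p(S) itself (``"gain"``), and the design maximizing the magnitude of its
entropy term -p log p (``"entropy"``), which peaks where p = 1/e and thus
rewards designs that are informative without being redundant.  Ties resolve
to the shortest duration (the cheapest test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .information import CovarianceModel
from .models import LoadProtocol, MaterialParams, count_samples, hypothesis
from .parameters import ParameterBounds
from .reconstruction import DEFAULT_N, reconstruct
from .synthetic import DEFAULT_NOISE, DEFAULT_TRUTH, NoiseSpec, generate

__all__ = [
    "DesignScan",
    "default_design_grid",
    "design_gain",
    "entropy_terms",
    "optimal_design",
]

DEFAULT_RANGE = (0.2, 5.0)
DEFAULT_POINTS = 25
DEFAULT_REPLICATES = 8
DEFAULT_CRITERION = "gain"


def default_design_grid(
    lo: float = DEFAULT_RANGE[0],
    hi: float = DEFAULT_RANGE[1],
    points: int = DEFAULT_POINTS,
) -> np.ndarray:
    """Log-spaced grid of candidate half-durations T (s)."""
    return np.geomspace(lo, hi, points)


def entropy_terms(p: Sequence[float], base: float = math.e) -> tuple[np.ndarray, float]:
    """Per-design entropy terms p*log_b(p) and the Shannon total -sum p*log_b(p).

    ``p`` must be normalized; 0*log(0) is taken as 0.  Base 2 gives bits,
    e nats, 10 hartleys.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("design probabilities must be nonnegative and sum to 1")
    terms = np.zeros_like(p)
    nz = p > 0
    terms[nz] = p[nz] * np.log(p[nz]) / math.log(base)
    return terms, float(-terms.sum())


@dataclass
class DesignScan:
    """Result of a scan of the design grid."""

    durations: np.ndarray        # candidate half-durations T (s)
    gains: np.ndarray            # f(S): replicate-averaged evidence per design
    std_errors: np.ndarray       # MC + replicate standard error of each gain
    plausibilities: np.ndarray   # p(S), sums to 1 over the grid
    entropy: np.ndarray          # per-design terms p * log p (literal, signed)
    entropy_total: float         # Shannon total -sum p log p
    log_base: float
    criterion: str
    replicates: int
    n_samples: int

    @property
    def optimal(self) -> float:
        return optimal_design(self)


def optimal_design(scan: DesignScan) -> float:
    """Optimal duration under the scan's criterion; ties -> shortest test."""
    if scan.durations.size == 0:
        raise ValueError("empty design scan")
    if scan.criterion == "gain":
        score = scan.plausibilities
    elif scan.criterion == "entropy":
        score = -scan.entropy  # -p log p, nonnegative, peaks at p = 1/e
    else:
        raise ValueError(f"unknown design criterion {scan.criterion!r}")
    best = score.max()
    # ties (within float noise) resolve to the smallest duration
    idx = int(np.flatnonzero(score >= best * (1.0 - 1e-12))[0])
    return float(scan.durations[idx])


def design_gain(
    h="H1",
    truth: MaterialParams = DEFAULT_TRUTH,
    noise: NoiseSpec = DEFAULT_NOISE,
    bounds: Optional[dict[str, ParameterBounds]] = None,
    grid: Optional[Sequence[float]] = None,
    sigma_max: float = 1.0e6,
    dt_sample: float = 0.1,
    n_samples: int = DEFAULT_N,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    criterion: str = DEFAULT_CRITERION,
    log_base: float = math.e,
) -> DesignScan:
    """Scan candidate test durations and score each by information gain.

    For every grid duration T, ``replicates`` synthetic experiments are
    generated from the reference truth under the rescaled protocol
    (0 -> sigma_max -> 0 over 2T, sampled every ``dt_sample``), the evidence
    of hypothesis ``h`` is estimated on each with ``n_samples`` Monte-Carlo
    points, and the replicate mean becomes the gain f(T).  Fixed seeds make
    the whole scan reproducible.
    """
    h = hypothesis(h)
    grid = np.asarray(default_design_grid() if grid is None else grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty design grid")
    gains = np.empty(grid.size)
    ses = np.empty(grid.size)
    for i, T in enumerate(grid):
        protocol = LoadProtocol(sigma_max, float(T), dt_sample)
        if count_samples(protocol) < 2:
            raise ValueError(
                f"design T={T} yields fewer than two samples at dt={dt_sample}"
            )
        reps = np.empty(replicates)
        rep_se = np.empty(replicates)
        for r in range(replicates):
            ss = np.random.SeedSequence([int(seed), i, r])
            data_seed, mc_seed = ss.spawn(2)
            obs = generate(
                h, truth, protocol, noise=noise,
                seed=int(data_seed.generate_state(1)[0] % (2**31)),
            )
            ps = reconstruct(h, obs, bounds=bounds, n_samples=n_samples, seed=mc_seed)
            reps[r], rep_se[r] = ps.evidence()
        gains[i] = reps.mean()
        # replicate scatter plus averaged per-replicate MC error
        mc_var = np.mean(rep_se**2) / replicates
        rep_var = reps.var(ddof=1) / replicates if replicates > 1 else 0.0
        ses[i] = math.sqrt(mc_var + rep_var)
    total = gains.sum()
    if total <= 0:
        raise ValueError("all design gains are zero; check the noise model")
    p = gains / total
    terms, H = entropy_terms(p, base=log_base)
    return DesignScan(
        durations=grid,
        gains=gains,
        std_errors=ses,
        plausibilities=p,
        entropy=terms,
        entropy_total=H,
        log_base=log_base,
        criterion=criterion,
        replicates=replicates,
        n_samples=n_samples,
    )
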