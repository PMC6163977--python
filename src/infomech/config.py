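"""Run configuration (YAML/JSON) and reproducibility manifest."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .models import LoadProtocol, MaterialParams
from .parameters import ParameterBounds, default_bounds
from .synthetic import DEFAULT_NOISE, DEFAULT_TRUTH, NoiseSpec

__all__ = ["RunConfig", "load_config", "write_manifest"]

_PKG_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Resolved configuration of one run; every field has a working default.

    Defaults mirror the reference study conditions: H1 truth (mu = 1 MPa,
    eta = 10 MPa*s, A = 15 kPa), 2 s triangular test to 1 MPa sampled at
    10 Hz, stress-equivalent Gaussian noise of 10 kPa, 2^16 Monte-Carlo
    samples, decade-wide Jeffreys bounds.
    """

    hypotheses: list[str] = field(default_factory=lambda: ["H1", "H2", "H3", "H4", "H5"])
    bounds: dict[str, ParameterBounds] = field(default_factory=default_bounds)
    protocol: LoadProtocol = field(default_factory=LoadProtocol)
    truth: MaterialParams = field(default_factory=lambda: DEFAULT_TRUTH)
    truth_hypothesis: str = "H1"
    noise: NoiseSpec = field(default_factory=lambda: DEFAULT_NOISE)
    n_samples: int = 2**16
    seed: int = 0
    nbins: int = 64
    dt_int: float = 1e-3
    design_range: tuple[float, float] = (0.2, 5.0)
    design_points: int = 25
    design_replicates: int = 8
    design_criterion: str = "gain"

    def to_dict(self) -> dict:
        d = {
            "hypotheses": list(self.hypotheses),
            "bounds": {
                k: {"lower": b.lower, "upper": b.upper, "units": b.units}
                for k, b in self.bounds.items()
            },
            "protocol": asdict(self.protocol),
            "truth": {k: v for k, v in asdict(self.truth).items() if v is not None},
            "truth_hypothesis": self.truth_hypothesis,
            "noise": asdict(self.noise),
            "n_samples": self.n_samples,
            "seed": self.seed,
            "nbins": self.nbins,
            "dt_int": self.dt_int,
            "design_range": list(self.design_range),
            "design_points": self.design_points,
            "design_replicates": self.design_replicates,
            "design_criterion": self.design_criterion,
        }
        return d


def _bounds_from_dict(raw: dict) -> dict[str, ParameterBounds]:
    out = default_bounds()
    for name, spec in raw.items():
        out[name] = ParameterBounds(
            name, float(spec["lower"]), float(spec["upper"]), spec.get("units", "")
        )
    return out


def load_config(path: Optional[str]) -> RunConfig:
    """Load a YAML (or JSON — valid YAML) config file; absent keys keep defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "hypotheses" in raw:
        cfg.hypotheses = list(raw["hypotheses"])
    if "bounds" in raw:
        cfg.bounds = _bounds_from_dict(raw["bounds"])
    if "protocol" in raw:
        p = raw["protocol"]
        cfg.protocol = LoadProtocol(
            float(p.get("sigma_max", 1e6)),
            float(p.get("half_duration", 1.0)),
            float(p.get("dt_sample", 0.1)),
        )
    if "truth" in raw:
        cfg.truth = MaterialParams(**{k: float(v) for k, v in raw["truth"].items()})
    if "truth_hypothesis" in raw:
        cfg.truth_hypothesis = str(raw["truth_hypothesis"])
    if "noise" in raw:
        n = raw["noise"]
        cfg.noise = NoiseSpec(
            mode=n.get("mode", DEFAULT_NOISE.mode),
            magnitude=float(n.get("magnitude", DEFAULT_NOISE.magnitude)),
            floor=float(n.get("floor", DEFAULT_NOISE.floor)),
        )
    for key in ("n_samples", "seed", "nbins", "design_points", "design_replicates"):
        if key in raw:
            setattr(cfg, key, int(raw[key]))
    if "dt_int" in raw:
        cfg.dt_int = float(raw["dt_int"])
    if "design_range" in raw:
        lo, hi = raw["design_range"]
        cfg.design_range = (float(lo), float(hi))
    if "design_criterion" in raw:
        cfg.design_criterion = str(raw["design_criterion"])
    return cfg


def write_manifest(outdir, cfg: RunConfig, extra: Optional[dict] = None) -> Path:
    """Write the resolved configuration (plus package version) next to outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"package": "infomech", "version": _PKG_VERSION, "config": cfg.to_dict()}
    if extra:
        payload.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
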