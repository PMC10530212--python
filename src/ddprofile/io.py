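"""File I/O: dataset CSV schemas, curve/MLE persistence, run configuration.

All numeric output is serialized with 17 significant digits so a write/read
round trip reproduces values exactly; every output file gets a JSON sidecar
carrying the seed and the fully resolved configuration that produced it.
"""
from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd

from .cloning import MLEResult
from .curves import ProfileCurve
from .models import Dataset

__all__ = [
    "RunConfig",
    "read_config",
    "read_dataset",
    "write_dataset",
    "write_curve",
    "read_curve",
    "write_mle",
    "read_mle",
    "write_draws",
    "read_draws",
    "write_laplace_terms",
]

_FMT = "%.17g"


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fmt(x: float) -> str:
    return _FMT % float(x)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved settings for one pipeline run."""

    subcommand: str = "profile"
    model: str = "beta_iid"
    data: Optional[str] = None
    psi: Optional[str] = None
    component: Optional[str] = None
    algorithm: int = 2
    smoother: str = "quartic"
    chains: int = 64
    draws: int = 80
    warmup: int = 1000
    thin: int = 6
    k_schedule: tuple = (1, 2, 4, 8, 16)
    grid_points: int = 101
    seed: int = 0
    mle_file: Optional[str] = None
    out: str = "run"

    def __post_init__(self):
        if self.algorithm not in (1, 2):
            raise ValueError("algorithm must be 1 or 2")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        if self.chains < 1 or self.draws < 1 or self.thin < 1 \
                or self.warmup < 0 or self.grid_points < 2:
            raise ValueError("sampler/grid settings out of range")
        self.k_schedule = tuple(int(k) for k in self.k_schedule)

    def sampler_config(self, seed: Optional[int] = None):
        from .sampler import SamplerConfig
        return SamplerConfig(chains=self.chains, draws=self.draws,
                             warmup=self.warmup, thin=self.thin,
                             seed=self.seed if seed is None else seed)


def read_config(path: str) -> RunConfig:
    """Read a YAML/JSON run configuration; unknown keys are an error."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
    return RunConfig(**raw)


# --------------------------------------------------------------------------
# datasets
# --------------------------------------------------------------------------

_SCHEMAS = {
    "scalar": {"y"},
    "timeseries": {"t", "count"},
    "trials": {"trial", "n_c", "r_c", "n_t", "r_t"},
}


def _infer_kind(columns) -> str:
    cols = set(columns)
    for kind, schema in _SCHEMAS.items():
        if schema <= cols:
            return kind
    return "matrix"


def read_dataset(path: str, kind: Optional[str] = None) -> Dataset:
    """Read a dataset CSV; the schema is inferred from the columns unless
    given.  A ``<path>.meta.json`` sidecar, if present, populates ``meta``."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if kind is None:
        kind = _infer_kind(frame.columns)
    meta = {}
    side = path + ".meta.json"
    if os.path.exists(side):
        with open(side) as fh:
            meta = json.load(fh)
    return Dataset(kind, frame, meta=meta)


def write_dataset(path: str, data: Dataset) -> None:
    data.frame.to_csv(path, index=False, float_format=_FMT)
    if data.meta:
        _atomic_write(path + ".meta.json",
                      json.dumps(data.meta, indent=1, default=float))


# --------------------------------------------------------------------------
# curves, MLE results, Laplace terms
# --------------------------------------------------------------------------

def write_curve(prefix: str, curve: ProfileCurve) -> tuple[str, str]:
    """Write ``<prefix>.curve.csv`` (psi, log_profile; ascending psi) and a
    ``<prefix>.meta.json`` sidecar."""
    csv_path = prefix + ".curve.csv"
    lines = ["psi,log_profile"]
    for p, v in zip(curve.psi_grid, curve.logpl):
        lines.append(f"{_fmt(p)},{_fmt(v)}")
    _atomic_write(csv_path, "\n".join(lines) + "\n")
    meta_path = prefix + ".meta.json"
    meta = {"method": curve.method, **curve.meta}
    _atomic_write(meta_path, json.dumps(meta, indent=1, default=float))
    return csv_path, meta_path


def read_curve(prefix: str) -> ProfileCurve:
    frame = pd.read_csv(prefix + ".curve.csv",
                        float_precision="round_trip")
    meta_path = prefix + ".meta.json"
    meta = {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
    method = meta.pop("method", "oracle")
    return ProfileCurve(frame["psi"].to_numpy(), frame["log_profile"].to_numpy(),
                        method=method, meta=meta)


def write_mle(path: str, mle: MLEResult) -> None:
    _atomic_write(path, json.dumps(mle.to_dict(), indent=1, default=float))


def read_mle(path: str) -> MLEResult:
    with open(path) as fh:
        d = json.load(fh)
    return MLEResult(
        theta_hat=np.asarray(d["theta_hat"]), cov=np.asarray(d["cov"]),
        K_used=int(d["K_used"]),
        diag_curve=[(int(k), float(v)) for k, v in d["diag_curve"]],
        converged=bool(d["converged"]), names=tuple(d.get("names", ())),
        seed=int(d.get("seed", 0)),
    )


def write_draws(prefix: str, draws) -> tuple[str, str]:
    """Persist posterior draws: ``<prefix>.draws.csv`` (parameter columns
    plus chain id) and a JSON sidecar with rhat/ess/seed/config."""
    csv_path = prefix + ".draws.csv"
    draws.to_frame().to_csv(csv_path, index=False, float_format=_FMT)
    cfg = draws.config
    side = {
        "names": list(draws.names), "K": int(draws.K),
        "rhat": draws.rhat.tolist(), "ess": draws.ess.tolist(),
        "seed": int(draws.seed), "accept_rate": float(draws.accept_rate),
        "warning": bool(draws.warning),
        "config": asdict(cfg) if cfg is not None else None,
    }
    if side["config"] is not None and side["config"]["init_theta"] is not None:
        side["config"]["init_theta"] = np.asarray(
            side["config"]["init_theta"]).tolist()
    meta_path = prefix + ".draws.json"
    _atomic_write(meta_path, json.dumps(side, indent=1, default=float))
    return csv_path, meta_path


def read_draws(prefix: str):
    from .sampler import PosteriorDraws
    frame = pd.read_csv(prefix + ".draws.csv",
                        float_precision="round_trip")
    with open(prefix + ".draws.json") as fh:
        side = json.load(fh)
    names = tuple(side["names"])
    return PosteriorDraws(
        draws=frame[list(names)].to_numpy(),
        chain_id=frame["chain"].to_numpy(), names=names, K=int(side["K"]),
        rhat=np.asarray(side["rhat"]), ess=np.asarray(side["ess"]),
        seed=int(side["seed"]), accept_rate=float(side["accept_rate"]),
        warning=bool(side["warning"]),
    )


def write_laplace_terms(path: str, terms: list) -> None:
    """CSV of Laplace factors: one row (psi, term1, term2, term3) per value."""
    lines = ["psi,term1,term2,term3"]
    for t in terms:
        lines.append(
            f"{_fmt(t.psi)},{_fmt(t.term1)},{_fmt(t.term2)},{_fmt(t.term3)}")
    _atomic_write(path, "\n".join(lines) + "\n")
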