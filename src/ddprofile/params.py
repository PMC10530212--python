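"""Canonical parameter spaces with supports and link transforms.

A model's canonical parameters live in a box-shaped support (each coordinate an
interval, possibly half-infinite).  Each coordinate carries a monotone *link*
mapping its support onto the whole real line; samplers and optimizers work on
the link scale, while priors and likelihoods are written on the natural scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit as _logit

_LINKS = ("identity", "log", "logit")


def _to_link(x: np.ndarray, link: str) -> np.ndarray:
    if link == "identity":
        return x
    if link == "log":
        return np.log(x)
    if link == "logit":
        return _logit(x)
    raise ValueError(f"unknown link {link!r}")


def _from_link(z: np.ndarray, link: str) -> np.ndarray:
    if link == "identity":
        return z
    if link == "log":
        with np.errstate(over="ignore"):  # inf is a legitimate image of +inf
            return np.exp(z)
    if link == "logit":
        return expit(z)
    raise ValueError(f"unknown link {link!r}")


def _log_jac(z: np.ndarray, link: str) -> np.ndarray:
    """log |d theta / d z| for one coordinate, on the link scale."""
    if link == "identity":
        return np.zeros_like(z)
    if link == "log":
        return z
    if link == "logit":
        # d/dz expit(z) = expit(z) * (1 - expit(z))
        return -np.logaddexp(0.0, z) - np.logaddexp(0.0, -z)
    raise ValueError(f"unknown link {link!r}")


_NATURAL_SUPPORT = {
    "identity": (-np.inf, np.inf),
    "log": (0.0, np.inf),
    "logit": (0.0, 1.0),
}


@dataclass(frozen=True)
class ParamSpace:
    """Named canonical parameters with per-coordinate supports and links."""

    names: tuple[str, ...]
    links: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "links", tuple(self.links))
        if len(self.names) != len(self.links):
            raise ValueError("names and links must have equal length")
        if self.dim < 1:
            raise ValueError("parameter space must have dimension >= 1")
        for lk in self.links:
            if lk not in _LINKS:
                raise ValueError(f"unknown link {lk!r}")
        if self.bounds is None:
            object.__setattr__(
                self, "bounds", tuple(_NATURAL_SUPPORT[lk] for lk in self.links)
            )
        else:
            bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
            if len(bounds) != self.dim:
                raise ValueError("bounds length mismatch")
            for (lo, hi), lk in zip(bounds, self.links):
                if not lo < hi:
                    raise ValueError(f"empty support ({lo}, {hi})")
            object.__setattr__(self, "bounds", bounds)

    @property
    def dim(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(
                f"no parameter named {name!r}; have {self.names}"
            ) from None

    def to_link(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        out = np.empty_like(theta)
        for j, lk in enumerate(self.links):
            out[..., j] = _to_link(theta[..., j], lk)
        return out

    def from_link(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = np.empty_like(z)
        for j, lk in enumerate(self.links):
            out[..., j] = _from_link(z[..., j], lk)
        return out

    def log_jacobian(self, z: np.ndarray) -> np.ndarray:
        """Sum over coordinates of log |d theta/d z| (for change of variables)."""
        z = np.asarray(z, dtype=float)
        out = np.zeros(z.shape[:-1], dtype=float)
        for j, lk in enumerate(self.links):
            out += _log_jac(z[..., j], lk)
        return out

    def in_support(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        ok = np.ones(theta.shape[:-1], dtype=bool)
        for j, (lo, hi) in enumerate(self.bounds):
            ok &= (theta[..., j] > lo) & (theta[..., j] < hi)
        return ok

    def default_box(self, half_width: float = 20.0) -> np.ndarray:
        """Wide finite box: the image of [-h, h] on the link scale, intersected
        with any explicit bounds.  Used for 'essentially flat' proper priors."""
        box = np.empty((self.dim, 2))
        for j, lk in enumerate(self.links):
            lo = float(_from_link(np.asarray(-half_width), lk))
            hi = float(_from_link(np.asarray(half_width), lk))
            lo = max(lo, self.bounds[j][0])
            hi = min(hi, self.bounds[j][1])
            box[j] = (lo, hi)
        return box
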