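"""Drift-diffusion parameterization of dendritic-spine volume dynamics.

Spine-head volume ``V`` (um^3) is modelled as a one-dimensional diffusion on
``[v_min, v_max]`` whose slow (day-scale) fluctuation SD and mean drift are
linear in the spine *surface area* proxy ``V**(2/3)``:

    sigma_slow(V) = slow_slope  * V**(2/3) + slow_intercept
    mu(V)         = drift_slope * V**(2/3) + drift_intercept

Minute-scale, actin-driven fluctuations ride on top of the slow process as
zero-mean observation noise with SD

    sigma_fast(V) = fast_slope * V**(2/3) + fast_intercept.

All rates are expressed per one observation interval of 2 days; sigma values
are um^3 per sqrt(interval), mu is um^3 per interval.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DriftDiffusionSpec",
    "WT_SPEC",
    "KO_SPEC",
    "VOLUME_EXPONENT",
]

#: fluctuation SD and drift scale with V**(2/3) (spine surface area), the
#: scaling found in adult neocortex; fixed, not a fit parameter.
VOLUME_EXPONENT = 2.0 / 3.0


@dataclass(frozen=True)
class DriftDiffusionSpec:
    """Coefficients of the volume-dependent drift and diffusion laws.

    Parameters
    ----------
    slow_slope, slow_intercept
        Slow-fluctuation SD law ``sigma_slow(V) = a*V**(2/3) + b``
        (um^3 per sqrt(2-d interval)).
    drift_slope, drift_intercept
        Mean drift law ``mu(V) = c*V**(2/3) + d`` (um^3 per 2-d interval).
    fast_slope, fast_intercept
        Fast-fluctuation SD law (um^3); the SD of the *difference* of two
        briefly spaced volume observations of the same spine.
    v_min, v_max
        Volume range of the model (um^3). ``v_min`` doubles as the
        elimination threshold.
    """

    slow_slope: float
    slow_intercept: float
    drift_slope: float = -0.12
    drift_intercept: float = 0.029
    fast_slope: float = 0.115
    fast_intercept: float = 0.0051
    v_min: float = 0.01
    v_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.v_min < self.v_max):
            raise ValueError(f"require 0 < v_min < v_max, got [{self.v_min}, {self.v_max}]")
        v = np.linspace(self.v_min, self.v_max, 256)
        if np.any(self.sigma_slow(v) <= 0):
            raise ValueError("sigma_slow must be positive on [v_min, v_max]")
        if np.any(self.sigma_fast(v) <= 0):
            raise ValueError("sigma_fast must be positive on [v_min, v_max]")

    # -- coefficient laws -------------------------------------------------
    def sigma_slow(self, v):
        """Slow-component SD at volume ``v`` (um^3 per sqrt interval)."""
        v = np.asarray(v, dtype=float)
        return self.slow_slope * v**VOLUME_EXPONENT + self.slow_intercept

    def sigma_fast(self, v):
        """Fast-component SD at volume ``v`` (um^3)."""
        v = np.asarray(v, dtype=float)
        return self.fast_slope * v**VOLUME_EXPONENT + self.fast_intercept

    def sigma_total(self, v):
        """Total per-interval SD: quadrature sum of slow and fast parts."""
        return np.sqrt(self.sigma_slow(v) ** 2 + self.sigma_fast(v) ** 2)

    def mu(self, v):
        """Mean drift at volume ``v`` (um^3 per interval)."""
        v = np.asarray(v, dtype=float)
        return self.drift_slope * v**VOLUME_EXPONENT + self.drift_intercept

    def drift_zero_crossing(self) -> float:
        """Volume at which the mean drift changes sign.

        Solving ``c*V**(2/3) + d = 0`` gives ``V = (d/-c)**(3/2)``; spines
        below this volume grow on average, spines above it shrink.
        """
        c, d = self.drift_slope, self.drift_intercept
        if c >= 0 or d <= 0:
            raise ValueError(
                f"drift has no zero crossing in (0, inf): slope={c}, intercept={d}"
            )
        return float((d / -c) ** 1.5)

    # -- (de)serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DriftDiffusionSpec":
        return cls(**json.loads(Path(path).read_text()))

    def replace(self, **changes) -> "DriftDiffusionSpec":
        d = asdict(self)
        d.update(changes)
        return DriftDiffusionSpec(**d)


#: Wild-type parameterization of the adult visual cortex:
#: sigma_slow anchored at (V=0.015, sigma=0.02), slope 0.198.
WT_SPEC = DriftDiffusionSpec(slow_slope=0.198, slow_intercept=0.0081)

#: Fmr1-knockout parameterization (fragile X model): same drift and fast
#: dynamics, steeper slow-fluctuation slope 0.278.
KO_SPEC = DriftDiffusionSpec(slow_slope=0.278, slow_intercept=0.0033)
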