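"""Parameter container for the relative-starting-time diffusion decision model.

The rstDDM describes a two-alternative food choice as noisy evidence
accumulation between two absorbing decision thresholds, fixed at -1 (right
option) and +1 (left option).  Two attribute values — the taste difference and
the health difference between the left and right foods — feed the drift rate,
and each attribute may start contributing at its own latency.  The relative
start time (``rst``) is the onset of the health attribute minus the onset of
the taste attribute, in seconds: a positive value means taste is considered
first.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace

#: Decision thresholds are fixed; only the starting point moves between them.
BOUNDS = (-1.0, 1.0)

#: Field order used for array round-trips (transform code, fitters, samplers).
PARAM_NAMES = ("noise", "sp_bias", "ndt", "rst", "w_taste", "w_health", "drift_bias")


@dataclass(frozen=True)
class RstDDMParams:
    """One subject/condition/session parameter set.

    Parameters
    ----------
    noise
        Standard deviation of the diffusion increment (a.u. per sqrt-second).
    sp_bias
        Starting point on (0, 1); 0.5 starts midway between the thresholds.
        Mapped affinely onto [-1, 1] as ``x0 = 2 * sp_bias - 1``.
    ndt
        Non-decision time in seconds (encoding + motor), added to the first
        passage time of the accumulator.
    rst
        Relative start time: onset(health) - onset(taste), seconds.
    w_taste, w_health
        Drift weights, a.u. per rating unit of the respective attribute
        difference.
    drift_bias
        Constant drift intercept, a.u./s, independent of both attributes.
    """

    noise: float = 1.0
    sp_bias: float = 0.5
    ndt: float = 0.5
    rst: float = 0.0
    w_taste: float = 0.0
    w_health: float = 0.0
    drift_bias: float = 0.0

    def __post_init__(self) -> None:
        if not (self.noise > 0):
            raise ValueError(f"noise must be > 0, got {self.noise}")
        if not (0.0 < self.sp_bias < 1.0):
            raise ValueError(f"sp_bias must lie in (0, 1), got {self.sp_bias}")
        if self.ndt < 0:
            raise ValueError(f"ndt must be >= 0, got {self.ndt}")
        for name in ("rst", "w_taste", "w_health", "drift_bias"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def x0(self) -> float:
        """Starting point mapped onto the [-1, 1] threshold interval."""
        return 2.0 * self.sp_bias - 1.0

    @property
    def onset_taste(self) -> float:
        """Taste onset within decision time; the earlier attribute starts at 0."""
        return 0.0 if self.rst >= 0 else -self.rst

    @property
    def onset_health(self) -> float:
        return self.rst if self.rst >= 0 else 0.0

    def with_(self, **changes) -> "RstDDMParams":
        return replace(self, **changes)

    def to_array(self):
        return [getattr(self, k) for k in PARAM_NAMES]

    @classmethod
    def from_array(cls, values) -> "RstDDMParams":
        return cls(**dict(zip(PARAM_NAMES, (float(v) for v in values))))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "RstDDMParams":
        return cls(**json.loads(s))
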