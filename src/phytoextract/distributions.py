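"""Declarative probability distributions for uncertain model inputs.

Uncertain inputs (BAF, BMP) are described by a :class:`DistributionSpec` of
one of three kinds:

* ``pert`` — Beta-PERT, the scaled Beta distribution parameterized by a
  minimum ``a``, most-likely value (mode) ``b`` and maximum ``c``, with shape
  parameters ``alpha1 = 1 + 4(b-a)/(c-a)`` and ``alpha2 = 1 + 4(c-b)/(c-a)``
  and mean ``(a + 4b + c) / 6``.
* ``normal`` — Normal(mean, sd), optionally truncated at zero by rejection
  resampling (negative draws are redrawn, not clipped — clipping would put a
  point mass at zero that distorts mode statistics).
* ``point`` — a degenerate constant.

Specs can be fitted from raw replicate measurements
(:func:`fit_from_replicates`) or from published summary statistics
(:func:`fit_from_summary`, :func:`pert_from_summary`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DistributionSpec",
    "pert_shape",
    "fit_from_replicates",
    "fit_from_summary",
    "pert_from_summary",
    "sample",
    "EXPECTED_HALF_RANGE",
]

# Expected range of a standard-normal sample of size n, in sd units
# (the d2 constant of statistical process control).  Used to place PERT
# endpoints when only (mean, sd, n) are published.
_D2 = {2: 1.128, 3: 1.693, 4: 2.059, 5: 2.326, 6: 2.534, 7: 2.704,
       8: 2.847, 9: 2.970, 10: 3.078, 12: 3.258, 15: 3.472, 20: 3.735,
       25: 3.931}

EXPECTED_HALF_RANGE: Mapping[int, float] = {n: d / 2 for n, d in _D2.items()}


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain input: a distribution kind plus its parameters.

    ``params`` holds ``{"min","mode","max"}`` for ``pert``,
    ``{"mean","sd"}`` for ``normal`` and ``{"value"}`` for ``point``.
    """

    kind: str
    params: Mapping[str, float] = field(default_factory=dict)
    truncate_at_zero: bool = False

    def __post_init__(self) -> None:
        p = self.params
        if self.kind == "pert":
            a, b, c = p["min"], p["mode"], p["max"]
            if not (a <= b <= c and a < c):
                raise ValueError("PERT requires min <= mode <= max and min < max")
        elif self.kind == "normal":
            if p["sd"] < 0:
                raise ValueError("sd must be non-negative")
        elif self.kind == "point":
            if "value" not in p:
                raise ValueError("point spec requires a value")
        else:
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    def mean(self) -> float:
        """Analytic mean of the distribution actually sampled."""
        p = self.params
        if self.kind == "point":
            return float(p["value"])
        if self.kind == "pert":
            return (p["min"] + 4 * p["mode"] + p["max"]) / 6.0
        mu, sd = p["mean"], p["sd"]
        if not self.truncate_at_zero or sd == 0:
            return float(mu)
        # zero-truncated normal mean
        alpha = -mu / sd
        return float(mu + sd * stats.norm.pdf(alpha) / stats.norm.sf(alpha))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "params": dict(self.params),
            "truncate_at_zero": self.truncate_at_zero,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        return cls(
            kind=d["kind"],
            params=dict(d["params"]),
            truncate_at_zero=bool(d.get("truncate_at_zero", False)),
        )

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls(kind="point", params={"value": float(value)})

    @classmethod
    def pert(cls, a: float, b: float, c: float) -> "DistributionSpec":
        return cls(kind="pert", params={"min": float(a), "mode": float(b), "max": float(c)})

    @classmethod
    def normal(cls, mean: float, sd: float, truncate_at_zero: bool = True) -> "DistributionSpec":
        return cls(kind="normal", params={"mean": float(mean), "sd": float(sd)},
                   truncate_at_zero=truncate_at_zero)


def pert_shape(a: float, b: float, c: float) -> tuple[float, float]:
    """Shape parameters (alpha1, alpha2) of the Beta-PERT scaled to [a, c]."""
    if a > b or b > c:
        raise ValueError("PERT requires min <= mode <= max")
    if a == c:
        raise ValueError("degenerate PERT (min == max); use a point spec")
    span = c - a
    return 1.0 + 4.0 * (b - a) / span, 1.0 + 4.0 * (c - b) / span


def fit_from_replicates(values: Sequence[float]) -> DistributionSpec:
    """Fit a Beta-PERT spec to raw replicate measurements.

    Endpoints are the sample min and max; the mode is solved from the PERT
    mean identity ``b = (6*mean - a - c) / 4`` (clamped into [a, c]) so the
    fitted distribution preserves the sample mean.  An empirical mode of a
    handful of replicates would be ill-defined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 replicate values")
    if not np.all(np.isfinite(x)):
        raise ValueError("replicate values must be finite")
    if np.any(x < 0):
        raise ValueError("replicate values must be non-negative")
    a, c = float(x.min()), float(x.max())
    if a == c:
        return DistributionSpec.point(a)
    b = (6.0 * float(x.mean()) - a - c) / 4.0
    return DistributionSpec.pert(a, min(max(b, a), c), c)


def fit_from_summary(mean: float, sd: float) -> DistributionSpec:
    """Zero-truncated Normal spec from a published mean +/- SD."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return DistributionSpec.point(mean)
    return DistributionSpec.normal(mean, sd, truncate_at_zero=True)


def pert_from_summary(mean: float, sd: float, n: int) -> DistributionSpec:
    """Beta-PERT spec from a published mean +/- SD of an n-sample.

    The publication rule for PERT inputs is min/mode/max of the underlying
    sample; when only (mean, sd, n) survive into print, the endpoints are
    placed at the expected sample range of n observations,
    ``mean +/- d2(n)/2 * sd`` (d2: expected-range constant), the minimum is
    floored at zero, and the mode is solved from the PERT mean identity so
    the spec preserves the published mean.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return DistributionSpec.point(mean)
    if n not in EXPECTED_HALF_RANGE:
        ns = sorted(EXPECTED_HALF_RANGE)
        n = min(ns, key=lambda m: abs(m - n))
    f = EXPECTED_HALF_RANGE[n]
    a = max(mean - f * sd, 0.0)
    c = mean + f * sd
    b = (6.0 * mean - a - c) / 4.0
    return DistributionSpec.pert(a, min(max(b, a), c), c)


def sample(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` non-negative values from a spec, reproducibly per rng state.

    Truncated-normal draws use rejection resampling.  A spec whose rejection
    acceptance probability is below 1% (mean < -2.33 sd) is unusable and
    raises.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = spec.params
    if spec.kind == "point":
        return np.full(n, float(p["value"]))
    if spec.kind == "pert":
        a, c = p["min"], p["max"]
        a1, a2 = pert_shape(a, p["mode"], c)
        return a + (c - a) * rng.beta(a1, a2, size=n)
    mu, sd = p["mean"], p["sd"]
    if sd == 0:
        return np.full(n, float(mu))
    if not spec.truncate_at_zero:
        return rng.normal(mu, sd, size=n)
    if stats.norm.sf(-mu / sd) < 0.01:
        raise ValueError("truncated-normal acceptance probability below 1%")
    out = np.empty(0)
    while out.size < n:
        x = rng.normal(mu, sd, size=n)
        out = np.concatenate([out, x[x >= 0]])
    return out[:n]
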