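"""Monte Carlo propagation of input uncertainty through the mass-balance models.

Each iteration draws the four uncertain inputs (BAF and BMP for stems and
leaves) from their distribution specs, evaluates the extraction potential E,
the removal rate k and the remediation times of both models, and the result
is summarized per output by its most-likely value (mode), mean, and the 5th,
50th and 95th percentiles.  Spearman rank correlations between input and
output draw vectors identify the inputs contributing most to output
uncertainty.

Remediation times are summarized from per-draw times, not from the
summarized rate: for skewed laws mode(t) != t(mode(k)), and the per-draw
summarization is what produces the wide uncertainty intervals these models
are meant to communicate.

Draws with a zero extraction potential yield infinite times; they are
excluded from summaries and their fraction is reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import SoilCompartment
from .distributions import DistributionSpec, sample

__all__ = [
    "INPUT_NAMES",
    "OUTPUT_NAMES",
    "SimulationConfig",
    "SimulationResult",
    "run_simulation",
    "estimate_mode",
    "percentile_interval",
    "summarize",
    "spearman_sensitivity",
]

INPUT_NAMES = ("baf_stem", "baf_leaves", "bmp_stem", "bmp_leaves")
OUTPUT_NAMES = ("e", "k", "t_linear", "t_exponential")

DEFAULT_ITERATIONS = 10_000
DEFAULT_SEED = 20240605


@dataclass(frozen=True)
class SimulationConfig:
    """Inputs of one Monte Carlo run."""

    soil: SoilCompartment
    input_specs: Mapping[str, DistributionSpec]
    n_iterations: int = DEFAULT_ITERATIONS
    seed: int = DEFAULT_SEED
    model: str = "both"           # linear | exponential | both
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iterations < 100:
            raise ValueError("need at least 100 iterations")
        missing = set(INPUT_NAMES) - set(self.input_specs)
        if missing:
            raise ValueError(f"missing input specs: {sorted(missing)}")
        if self.model not in ("linear", "exponential", "both"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.efficiency <= 0:
            raise ValueError("efficiency must be positive")


@dataclass
class SimulationResult:
    """Per-iteration draws plus per-output summaries and sensitivities."""

    draws: pd.DataFrame
    summaries: dict[str, dict[str, float]]
    sensitivity: dict[str, list[dict]]
    meta: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "summaries": self.summaries,
            "sensitivity": self.sensitivity,
            "meta": self.meta,
        }


def estimate_mode(draws: np.ndarray) -> float:
    """Most-likely value of a sample: argmax of a Gaussian kernel density.

    Bandwidth follows Silverman's rule of thumb with the interquartile-range
    guard, ``0.9 * min(sd, IQR/1.349) * n**(-1/5)``, which keeps the
    estimate sharp for the heavy right tails these models produce.  The
    density is evaluated on a 512-point grid from the sample minimum to the
    99th percentile; the grid is trimmed (the sample is not) so that a few
    extreme draws cannot starve the bulk of the distribution of grid
    resolution.  Deterministic given the draws.
    """
    x = np.asarray(draws, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError("need at least 100 finite draws")
    sd = float(x.std())
    if sd == 0:
        return float(x[0])
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    sigma = min(sd, iqr / 1.349) if iqr > 0 else sd
    bw = 0.9 * sigma * x.size ** (-0.2)
    kde = stats.gaussian_kde(x, bw_method=bw / sd)
    grid = np.linspace(x.min(), np.percentile(x, 99), 512)
    return float(grid[np.argmax(kde(grid))])


def percentile_interval(
    draws: np.ndarray, lo: float = 5.0, hi: float = 95.0
) -> tuple[float, float]:
    """Empirical (p_lo, p_hi) quantiles of the finite draws."""
    x = np.asarray(draws, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError("need at least 100 finite draws")
    p = np.percentile(x, [lo, hi])
    return float(p[0]), float(p[1])


def summarize(draws: np.ndarray) -> dict[str, float]:
    """Mode, mean and percentile summary of one output's draw vector."""
    x = np.asarray(draws, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 100:
        # degenerate output (e.g. all-zero extraction): no defined summary
        return {
            "mode": float("nan"), "mean": float("nan"), "p5": float("nan"),
            "p50": float("nan"), "p95": float("nan"),
            "frac_nonfinite": float(1.0 - finite.size / x.size),
        }
    p5, p95 = percentile_interval(finite)
    return {
        "mode": estimate_mode(finite),
        "mean": float(finite.mean()),
        "p5": p5,
        "p50": float(np.percentile(finite, 50)),
        "p95": p95,
        "frac_nonfinite": float(1.0 - finite.size / x.size),
    }


def run_simulation(cfg: SimulationConfig) -> SimulationResult:
    """Propagate the input distributions through both models.

    Identical config and seed give an identical result.  A run in which
    more than half of the remediation-time draws are non-finite is flagged
    degenerate.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_iterations
    sc = cfg.soil

    cols: dict[str, np.ndarray] = {
        name: sample(cfg.input_specs[name], n, rng) for name in INPUT_NAMES
    }
    c = sc.c_soil_i
    e = cfg.efficiency * (
        cols["baf_stem"] * c * cols["bmp_stem"]
        + cols["baf_leaves"] * c * cols["bmp_leaves"]
    )
    m_i, m_f = sc.m_soil_i, sc.m_soil_f
    k = e / m_i
    with np.errstate(divide="ignore"):
        t_lin = np.where(e > 0, (m_i - m_f) / e, np.inf)
        t_exp = (
            np.where(k > 0, np.log(m_i / m_f) / k, np.inf)
            if m_f > 0
            else np.full(n, np.inf)
        )
    cols["e"] = e
    cols["k"] = k
    if cfg.model in ("linear", "both"):
        cols["t_linear"] = t_lin
    if cfg.model in ("exponential", "both"):
        cols["t_exponential"] = t_exp

    draws = pd.DataFrame(cols)
    out_names = [o for o in OUTPUT_NAMES if o in draws]
    summaries = {o: summarize(draws[o].to_numpy()) for o in out_names}

    degenerate = any(s["frac_nonfinite"] > 0.5 for s in summaries.values())

    result = SimulationResult(
        draws=draws,
        summaries=summaries,
        sensitivity={},
        meta={
            "seed": cfg.seed,
            "n_iterations": n,
            "model": cfg.model,
            "efficiency": cfg.efficiency,
            "soil": {
                "c_soil_i": sc.c_soil_i,
                "c_soil_f": sc.c_soil_f,
                "rho": sc.rho,
                "depth": sc.depth,
                "area": sc.area,
            },
            "m_soil_i": m_i,
            "m_soil_f": m_f,
            "input_specs": {
                name: cfg.input_specs[name].to_dict() for name in INPUT_NAMES
            },
            "degenerate": degenerate,
        },
    )
    result.sensitivity = {
        o: spearman_sensitivity(result, o) for o in out_names
    }
    return result


def spearman_sensitivity(result: SimulationResult, output: str) -> list[dict]:
    """Spearman rank correlation of each input against one output.

    Returns one record per input, sorted by absolute correlation
    descending.  Constant inputs (point specs) have no ranks; they are
    reported as rho = 0 with ``constant=True``.
    """
    draws = result.draws
    y = draws[output].to_numpy()
    finite = np.isfinite(y)
    if finite.sum() < 2:
        # degenerate output (no finite draws): no ranks to correlate
        return [
            {"input": name, "rho": 0.0, "constant": True} for name in INPUT_NAMES
        ]
    records = []
    for name in INPUT_NAMES:
        x = draws[name].to_numpy()[finite]
        if np.ptp(x) == 0:
            records.append({"input": name, "rho": 0.0, "constant": True})
            continue
        rho = stats.spearmanr(x, y[finite]).statistic
        records.append({"input": name, "rho": float(rho), "constant": False})
    records.sort(key=lambda r: abs(r["rho"]), reverse=True)
    return records
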