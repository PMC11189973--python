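"""Human-readable rendering of simulation results.

All numbers inside the library are unrounded floats; 3-significant-figure
rounding and percent formatting happen here only.  Years of 1000 or more
are grouped with a thin space ("3 570"); machine artifacts (CSV/JSON)
always carry unformatted floats.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

from .monte_carlo import SimulationResult

__all__ = ["sig3", "format_years", "format_percent", "render_report"]

_THIN_SPACE = " "


def sig3(x: float) -> float:
    """Round to three significant figures (half away from zero, as printed
    tables do, not banker's rounding)."""
    if x == 0 or not math.isfinite(x):
        return x
    digits = 2 - int(math.floor(math.log10(abs(x))))
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def format_years(t: float) -> str:
    """Render a time in years: 3 significant figures, thin-space thousands."""
    if not math.isfinite(t):
        return "inf"
    r = sig3(t)
    if abs(r) >= 1000:
        return f"{int(round(r)):,}".replace(",", _THIN_SPACE)
    return f"{r:g}"


def format_percent(k: float) -> str:
    """Render a per-year fraction as a percentage, 3 significant figures."""
    if not math.isfinite(k):
        return "inf"
    return f"{sig3(k * 100.0):g}%"


_LABELS = {
    "e": ("E (mg/yr)", "{:g}"),
    "k": ("k (%/yr)", None),          # percent formatting
    "t_linear": ("t linear (yr)", None),
    "t_exponential": ("t exponential (yr)", None),
}


def _fmt(output: str, value: float) -> str:
    if output == "k":
        return format_percent(value)
    if output.startswith("t_"):
        return format_years(value)
    return f"{sig3(value):g}"


def render_report(result: SimulationResult) -> str:
    """Deterministic text table: mode with [p5; p95] brackets per output."""
    meta = result.meta
    lines = [
        f"Monte Carlo simulation: {meta['n_iterations']} iterations, "
        f"seed {meta['seed']}, model {meta['model']}",
        f"soil: c_i = {meta['soil']['c_soil_i']:g} mg/kg, "
        f"c_f = {meta['soil']['c_soil_f']:g} mg/kg, "
        f"m_i = {format_years(meta['m_soil_i'])} mg, "
        f"m_f = {format_years(meta['m_soil_f'])} mg",
    ]
    width = max(len(label) for label, _ in _LABELS.values()) + 2
    for output, summ in result.summaries.items():
        label = _LABELS.get(output, (output, None))[0]
        body = (
            f"{_fmt(output, summ['mode'])} "
            f"[{_fmt(output, summ['p5'])}; {_fmt(output, summ['p95'])}]"
        )
        extra = ""
        if summ["frac_nonfinite"] > 0:
            extra = f"  ({summ['frac_nonfinite']:.2%} non-finite draws excluded)"
        lines.append(f"{label:<{width}}{body}{extra}")
    return "\n".join(lines)
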