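"""Deterministic phytoextraction mass-balance models.

Two simplified models of contaminant removal by harvesting plant tissue:

* **linear steady-state** — the annual extraction potential ``E`` (mg/yr) is
  held constant, so the soil contaminant mass declines linearly and the
  remediation time is ``(m_i - m_f) / E``.  This is the theoretical minimum
  time.
* **first-order exponential decay** — removal is proportional to the
  remaining mass, ``m(t) = m_i * exp(-k t)`` with the removal rate
  ``k = E / m_i`` (fraction of the initial soil mass removed per year), so
  the remediation time is ``ln(m_i / m_f) / k``.

``E`` is driven by two aggregated, empirically determined plant variables per
harvestable tissue (stems and leaves): the bioaccumulation factor ``BAF``
(tissue concentration / soil concentration, both mg/kg dry weight) and the
harvestable biomass production ``BMP`` (kg dw per m^2 per year).

Units: concentrations in mg/kg dw, bulk density in kg/m^3, geometry in m,
masses in mg, times in years.  ``k`` is stored as a fraction per year
throughout the library; it is rendered as a percentage only at the reporting
boundary (see :mod:`phytoextract.report`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SoilCompartment",
    "TissueUptake",
    "ModelOutputs",
    "soil_mass",
    "plant_concentration",
    "extraction_potential",
    "removal_rate",
    "time_linear",
    "time_exponential",
    "mass_at_time",
    "translocation_factor",
    "stem_from_root",
    "run_deterministic",
]


@dataclass(frozen=True)
class SoilCompartment:
    """The soil volume undergoing phytoextraction.

    Parameters
    ----------
    c_soil_i : float
        Initial contaminant concentration, mg/kg dw.
    c_soil_f : float
        Target (final) concentration, mg/kg dw.  Must satisfy
        ``0 <= c_soil_f < c_soil_i``.
    rho : float
        Soil bulk density, kg/m^3 (default 1500).
    depth : float
        Depth of the treated soil layer, m (default 0.35).
    area : float
        Treated area, m^2 (default 1, so masses are per square metre).
    """

    c_soil_i: float
    c_soil_f: float = 1.0
    rho: float = 1500.0
    depth: float = 0.35
    area: float = 1.0

    def __post_init__(self) -> None:
        if self.c_soil_i <= 0:
            raise ValueError("initial soil concentration must be positive")
        if not 0 <= self.c_soil_f < self.c_soil_i:
            raise ValueError("target concentration must satisfy 0 <= c_f < c_i")
        for name in ("rho", "depth", "area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def volume(self) -> float:
        """Treated soil volume, m^3."""
        return self.area * self.depth

    @property
    def m_soil_i(self) -> float:
        """Initial contaminant mass, mg."""
        return soil_mass(self, self.c_soil_i)

    @property
    def m_soil_f(self) -> float:
        """Contaminant mass at the target concentration, mg."""
        return soil_mass(self, self.c_soil_f)


@dataclass(frozen=True)
class TissueUptake:
    """Per-tissue bioaccumulation factors and biomass production.

    BAF is dimensionless ((mg/kg plant dw) / (mg/kg soil dw)); BMP is
    kg dw per m^2 per year.  Only stems and leaves are harvest
    compartments; roots enter the workflow only through the translocation
    factor and fruits are not modelled.
    """

    baf_stem: float
    baf_leaves: float
    bmp_stem: float
    bmp_leaves: float

    def __post_init__(self) -> None:
        for name in ("baf_stem", "baf_leaves", "bmp_stem", "bmp_leaves"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ModelOutputs:
    """Derived outputs of one deterministic model evaluation."""

    e: float                # extraction potential, mg/yr
    k: float                # removal rate, fraction per year
    t_linear: float         # years
    t_exponential: float    # years
    m_soil_i: float         # mg
    m_soil_f: float         # mg


def soil_mass(sc: SoilCompartment, c: float) -> float:
    """Contaminant mass (mg) in the compartment at soil concentration ``c``.

    ``m = rho * V * c`` with rho in kg/m^3, V in m^3 and c in mg/kg.
    """
    if c < 0:
        raise ValueError("soil concentration must be non-negative")
    return sc.rho * sc.volume * c


def plant_concentration(baf: float, c_soil: float) -> float:
    """Tissue concentration (mg/kg dw) implied by a BAF at a soil concentration."""
    if c_soil <= 0:
        raise ValueError("soil concentration must be positive")
    if baf < 0:
        raise ValueError("BAF must be non-negative")
    return baf * c_soil


def extraction_potential(
    u: TissueUptake, c_soil_i: float, efficiency: float = 1.0
) -> float:
    """Annual contaminant extraction potential E (mg/yr per BMP area basis).

    ``E = eff * [(BAF_stem * c_i) * BMP_stem + (BAF_leaves * c_i) * BMP_leaves]``

    ``efficiency`` is a multiplicative factor on E (scenario analyses use it
    to encode concentration-dependent uptake efficiency).
    """
    if c_soil_i < 0:
        raise ValueError("soil concentration must be non-negative")
    if efficiency <= 0:
        raise ValueError("efficiency must be positive")
    stems = u.baf_stem * c_soil_i * u.bmp_stem
    leaves = u.baf_leaves * c_soil_i * u.bmp_leaves
    return efficiency * (stems + leaves)


def removal_rate(e: float, m_soil_i: float) -> float:
    """Fraction of the initial soil contaminant mass removed per year."""
    if m_soil_i <= 0:
        raise ValueError("initial soil mass must be positive")
    if e < 0:
        raise ValueError("extraction potential must be non-negative")
    return e / m_soil_i


def time_linear(m_i: float, m_f: float, e: float) -> float:
    """Years to go from mass ``m_i`` to ``m_f`` at constant extraction ``e``.

    Returns ``+inf`` when ``e == 0`` and mass must still decrease; Monte
    Carlo draws can legitimately produce a zero extraction potential after
    truncation, and summaries handle the infinite sentinel explicitly.
    """
    if m_f > m_i:
        raise ValueError("final mass cannot exceed initial mass")
    if m_f < 0:
        raise ValueError("final mass must be non-negative")
    if m_i == m_f:
        return 0.0
    if e == 0:
        return math.inf
    return (m_i - m_f) / e


def time_exponential(m_i: float, m_f: float, k: float) -> float:
    """Years to go from ``m_i`` to ``m_f`` under first-order decay at rate ``k``.

    ``t = ln(m_i / m_f) / k``.  The exponential model never reaches a zero
    final mass, so ``m_f == 0`` is a domain error; ``k == 0`` returns the
    ``+inf`` sentinel (see :func:`time_linear`).
    """
    if m_f > m_i:
        raise ValueError("final mass cannot exceed initial mass")
    if m_f <= 0:
        raise ValueError("exponential decay never reaches a zero final mass")
    if m_i == m_f:
        return 0.0
    if k == 0:
        return math.inf
    return math.log(m_i / m_f) / k


def mass_at_time(m_i: float, k: float, t: float, model: str = "exponential") -> float:
    """Soil contaminant mass (mg) remaining after ``t`` years.

    ``model="exponential"`` gives ``m_i * exp(-k t)``; ``model="linear"``
    gives the constant-extraction counterpart ``max(0, m_i * (1 - k t))``.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if model == "exponential":
        return m_i * math.exp(-k * t)
    if model == "linear":
        return max(0.0, m_i * (1.0 - k * t))
    raise ValueError(f"unknown model {model!r}")


def translocation_factor(c_stem: float, c_root: float) -> float:
    """Stem-to-root concentration ratio, TF = C_stem / C_root."""
    if c_root <= 0:
        raise ValueError("root concentration must be positive")
    if c_stem < 0:
        raise ValueError("stem concentration must be non-negative")
    return c_stem / c_root


def stem_from_root(tf: float, c_root: float) -> float:
    """Estimate a stem concentration from a root concentration and a TF.

    Inverse companion of :func:`translocation_factor`; used to repair
    harvest records whose above-ground tissue was lost (e.g. consumed by
    pests) but whose roots were still sampled.
    """
    if tf < 0:
        raise ValueError("translocation factor must be non-negative")
    if c_root < 0:
        raise ValueError("root concentration must be non-negative")
    return tf * c_root


def run_deterministic(
    u: TissueUptake, sc: SoilCompartment, efficiency: float = 1.0
) -> ModelOutputs:
    """Evaluate both models once for fixed inputs."""
    m_i = sc.m_soil_i
    m_f = sc.m_soil_f
    e = extraction_potential(u, sc.c_soil_i, efficiency)
    k = removal_rate(e, m_i)
    return ModelOutputs(
        e=e,
        k=k,
        t_linear=time_linear(m_i, m_f, e),
        t_exponential=time_exponential(m_i, m_f, k) if m_f > 0 else math.inf,
        m_soil_i=m_i,
        m_soil_f=m_f,
    )
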