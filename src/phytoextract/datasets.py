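"""Packaged parameter datasets and a synthetic field-study generator.

Two kinds of input data ship with the package:

* published summary statistics (mean, SD, n) of BAF and BMP per harvestable
  tissue, for a site-specific pumpkin (*Cucurbita pepo*) field experiment on
  aged DDX-contaminated soil, a literature-derived dataset for the same
  species, and per-DDT-metabolite site datasets;
* :func:`generate_synthetic_study`, which fabricates raw per-plot field
  records (soil/tissue concentrations, tissue dry weights) around known
  true parameter values, to exercise the replicate-fitting path and
  parameter-recovery tests without any real raw data.

The default distribution family per variable (bounded Beta-PERT for
bioaccumulation factors of the literature dataset, zero-truncated Normal
elsewhere) is recorded in the packaged CSV and applied by
:meth:`Dataset.specs`; callers can override any variable's spec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .distributions import (
    DistributionSpec,
    fit_from_replicates,
    fit_from_summary,
    pert_from_summary,
)

__all__ = [
    "Dataset",
    "SyntheticTruth",
    "SyntheticFieldStudy",
    "load_dataset",
    "available_datasets",
    "generate_synthetic_study",
    "adjust_damaged_harvest",
]

_VARIABLES = ("baf_stem", "baf_leaves", "bmp_stem", "bmp_leaves")


def _table() -> pd.DataFrame:
    with resources.files("phytoextract.data").joinpath("parameters.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class Dataset:
    """One named parameter dataset: summary stats and family per variable."""

    name: str
    rows: pd.DataFrame
    n: int
    c_soil_i: float

    def summary(self, variable: str) -> tuple[float, float | None]:
        """(mean, sd) for e.g. ``baf_stem``; sd is None for point values."""
        var, tissue = variable.rsplit("_", 1)
        tissue = {"stem": "stem", "leaves": "leaves"}[tissue]
        row = self.rows[(self.rows.variable == var) & (self.rows.tissue == tissue)]
        if row.empty:
            raise KeyError(variable)
        mean = float(row["mean"].iloc[0])
        sd = row["sd"].iloc[0]
        return mean, (None if pd.isna(sd) else float(sd))

    def spec(self, variable: str) -> DistributionSpec:
        var, tissue = variable.rsplit("_", 1)
        row = self.rows[(self.rows.variable == var) & (self.rows.tissue == tissue)]
        if row.empty:
            raise KeyError(variable)
        family = row["family"].iloc[0]
        mean, sd = self.summary(variable)
        if family == "point" or sd is None:
            return DistributionSpec.point(mean)
        if family == "pert":
            return pert_from_summary(mean, sd, int(row["n"].iloc[0]))
        return fit_from_summary(mean, sd)

    def specs(self, **overrides: DistributionSpec) -> dict[str, DistributionSpec]:
        """Distribution specs for all four inputs, with optional overrides."""
        out = {v: self.spec(v) for v in _VARIABLES}
        unknown = set(overrides) - set(_VARIABLES)
        if unknown:
            raise KeyError(f"unknown variables: {sorted(unknown)}")
        out.update(overrides)
        return out

    def means(self) -> dict[str, float]:
        return {v: self.summary(v)[0] for v in _VARIABLES}


def available_datasets() -> list[str]:
    return sorted(_table().dataset.unique())


def load_dataset(name: str) -> Dataset:
    """Load a packaged dataset by name.

    Accepted names: ``site_specific``, ``literature`` and the per-metabolite
    datasets ``pp_ddt``, ``op_ddt``, ``pp_ddd``, ``pp_dde`` (optionally
    prefixed ``metabolite:``).
    """
    key = name.removeprefix("metabolite:")
    tbl = _table()
    rows = tbl[tbl.dataset == key]
    if rows.empty:
        raise KeyError(
            f"unknown dataset {name!r}; available: {sorted(tbl.dataset.unique())}"
        )
    return Dataset(
        name=key,
        rows=rows.reset_index(drop=True),
        n=int(rows["n"].iloc[0]),
        c_soil_i=float(rows["c_soil_i"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# synthetic field study


@dataclass(frozen=True)
class SyntheticTruth:
    """True parameter values a synthetic study is generated around."""

    baf_stem: float = 0.89
    baf_leaves: float = 0.134
    bmp_stem: float = 0.0783
    bmp_leaves: float = 0.190
    tf: float = 1.2               # stem/root concentration ratio
    c_soil: float = 10.0          # mg/kg dw
    plot_area: float = 1.0        # m^2

    def __post_init__(self) -> None:
        for name in ("baf_stem", "baf_leaves", "bmp_stem", "bmp_leaves",
                     "tf", "c_soil", "plot_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def baf_root(self) -> float:
        return self.baf_stem / self.tf


@dataclass
class SyntheticFieldStudy:
    """Per-plot records generated around a known truth."""

    records: pd.DataFrame
    truth: SyntheticTruth
    noise_cv: float
    seed: int

    def baf_replicates(self, tissue: str) -> np.ndarray:
        """Per-plot BAF values, c_tissue / c_soil."""
        r = self.records
        return (r[f"c_{tissue}"] / r["c_soil"]).to_numpy()

    def bmp_replicates(self, tissue: str) -> np.ndarray:
        """Per-plot biomass production, kg dw per m^2 per year."""
        r = self.records
        return (r[f"dw_{tissue}"] / r["area"]).to_numpy()

    def tf_replicates(self) -> np.ndarray:
        r = self.records
        return (r["c_stem"] / r["c_root"]).to_numpy()

    def fitted_specs(self) -> dict[str, DistributionSpec]:
        """Beta-PERT specs fitted to the per-plot replicate values."""
        return {
            "baf_stem": fit_from_replicates(self.baf_replicates("stem")),
            "baf_leaves": fit_from_replicates(self.baf_replicates("leaves")),
            "bmp_stem": fit_from_replicates(self.bmp_replicates("stem")),
            "bmp_leaves": fit_from_replicates(self.bmp_replicates("leaves")),
        }


def _lognormal_factors(cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative mean-1 lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate_synthetic_study(
    truth: SyntheticTruth = SyntheticTruth(),
    n_plots: int = 6,
    noise_cv: float = 0.3,
    seed: int = 0,
) -> SyntheticFieldStudy:
    """Fabricate per-plot field records around known true parameters.

    Concentrations and biomasses are positive and right-skewed in real
    field data, so plot-to-plot variation is modelled as multiplicative
    lognormal noise (mean 1, coefficient of variation ``noise_cv``) applied
    independently to each measured quantity.  Tissue concentrations follow
    ``c_tissue = BAF_tissue * c_soil`` on the plot's own soil concentration,
    so with ``noise_cv = 0`` the per-plot derived BAFs equal the truth
    exactly.  Reproducible per seed.
    """
    if n_plots < 3:
        raise ValueError("need at least 3 plots")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    c_soil = truth.c_soil * _lognormal_factors(noise_cv, n_plots, rng)
    rec = pd.DataFrame(
        {
            "plot": np.arange(1, n_plots + 1),
            "c_soil": c_soil,
            "c_stem": truth.baf_stem * c_soil * _lognormal_factors(noise_cv, n_plots, rng),
            "c_leaves": truth.baf_leaves * c_soil * _lognormal_factors(noise_cv, n_plots, rng),
            "c_root": truth.baf_root * c_soil * _lognormal_factors(noise_cv, n_plots, rng),
            "dw_stem": truth.bmp_stem * truth.plot_area * _lognormal_factors(noise_cv, n_plots, rng),
            "dw_leaves": truth.bmp_leaves * truth.plot_area * _lognormal_factors(noise_cv, n_plots, rng),
            "dw_root": truth.bmp_stem / truth.tf * truth.plot_area * _lognormal_factors(noise_cv, n_plots, rng),
            "area": truth.plot_area,
            "imputed_stem": False,
        }
    )
    return SyntheticFieldStudy(records=rec, truth=truth, noise_cv=noise_cv, seed=seed)


def adjust_damaged_harvest(
    study: SyntheticFieldStudy, tf_reference: float
) -> SyntheticFieldStudy:
    """Impute missing stem concentrations from roots via a translocation factor.

    Field harvests can lose above-ground tissue (e.g. to pests) while roots
    remain measurable; the stem concentration of such plots is estimated as
    ``TF * c_root`` using a reference TF (typically derived from an intact
    earlier season).  Imputed records are flagged; plots missing the root
    measurement as well are dropped with a warning.
    """
    if tf_reference <= 0:
        raise ValueError("tf_reference must be positive")
    rec = study.records.copy()
    missing_stem = rec["c_stem"].isna()
    if not missing_stem.any():
        return study
    missing_both = missing_stem & rec["c_root"].isna()
    if missing_both.any():
        warnings.warn(
            f"dropping {int(missing_both.sum())} plot(s) missing both stem and "
            "root concentrations",
            stacklevel=2,
        )
        rec = rec[~missing_both]
        missing_stem = rec["c_stem"].isna()
    rec.loc[missing_stem, "c_stem"] = tf_reference * rec.loc[missing_stem, "c_root"]
    rec.loc[missing_stem, "imputed_stem"] = True
    return SyntheticFieldStudy(
        records=rec.reset_index(drop=True),
        truth=study.truth,
        noise_cv=study.noise_cv,
        seed=study.seed,
    )
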