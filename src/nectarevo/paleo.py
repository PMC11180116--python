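"""Paleotemperature series and clade-age / temperature models.

A global mean annual surface temperature (GMST) series on a uniform 0.2-My
grid spanning 100 Ma to the present provides the abiotic covariate: each
plant family is assigned the temperature prevailing at its crown age by
linear interpolation. Two model families probe the evolutionary depth of
the phylogenetic signal in nectar sucrose:

* clade-age models — fractional-binomial GLM of sucrose proportion on
  family (or order) crown age, optionally with a random order intercept;
* paleotemperature models — GLMM of sucrose proportion on the GMST at
  family origin, with family-within-order random intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm_engine import GlmError, ModelFit, ModelSpec, fit_glm, fit_glmm
from .phylo import Phylogeny, clade_crown_ages

__all__ = [
    "TemperatureSeries",
    "interpolate_temperature",
    "clade_age_model",
    "paleotemp_model",
    "attach_clade_ages",
]


class PaleoError(ValueError):
    """Invalid temperature series or query."""


@dataclass
class TemperatureSeries:
    """GMST per time point on a uniform grid, 100 Ma (oldest) to 0 (present).

    ``times_ma`` are ages in My before present, strictly decreasing;
    ``gmst_c`` the matching temperatures in degrees Celsius.
    """

    times_ma: np.ndarray
    gmst_c: np.ndarray

    def __post_init__(self) -> None:
        self.times_ma = np.asarray(self.times_ma, dtype=float)
        self.gmst_c = np.asarray(self.gmst_c, dtype=float)
        if self.times_ma.size != self.gmst_c.size:
            raise PaleoError("times and temperatures differ in length")
        if self.times_ma.size < 2:
            raise PaleoError("need at least two grid points")
        steps = np.diff(self.times_ma)
        if np.any(steps >= 0):
            raise PaleoError("time grid must be strictly decreasing (oldest first)")
        if not np.allclose(steps, steps[0], atol=1e-9):
            raise PaleoError("time grid must have a uniform step")
        if np.isnan(self.gmst_c).any():
            raise PaleoError("missing temperature values")

    @property
    def step(self) -> float:
        return float(-np.diff(self.times_ma)[0])

    @property
    def max_age(self) -> float:
        return float(self.times_ma[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ma": self.times_ma, "gmst_c": self.gmst_c})

    @classmethod
    def from_csv(cls, path) -> "TemperatureSeries":
        df = pd.read_csv(path)
        if not {"time_ma", "gmst_c"}.issubset(df.columns):
            raise PaleoError("temperature CSV needs columns time_ma,gmst_c")
        df = df.sort_values("time_ma", ascending=False)
        return cls(df["time_ma"].to_numpy(), df["gmst_c"].to_numpy())

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def interpolate_temperature(series: TemperatureSeries, age_ma) -> np.ndarray | float:
    """GMST at ``age_ma`` by piecewise-linear interpolation; no extrapolation."""
    age = np.asarray(age_ma, dtype=float)
    if np.any(age < 0) or np.any(age > series.max_age):
        bad = age[(age < 0) | (age > series.max_age)]
        raise PaleoError(
            f"age(s) {np.atleast_1d(bad)[:5].tolist()} outside the series range "
            f"[0, {series.max_age}]; extrapolation is not performed"
        )
    # np.interp wants ascending x
    out = np.interp(age, series.times_ma[::-1], series.gmst_c[::-1])
    return float(out) if np.isscalar(age_ma) else out


def attach_clade_ages(
    traits: pd.DataFrame, phylo: Phylogeny, level: str = "family"
) -> pd.DataFrame:
    """Add a ``{level}_age_ma`` column of crown ages to a species trait table.

    Species are mapped via the tree's clade annotations; one-species clades
    fall back to stem age (flagged by the phylo module with a warning).
    """
    ages = clade_crown_ages(phylo, level)
    idx = 0 if level == "family" else 1
    out = traits.copy()
    clade_of = {sp: fo[idx] for sp, fo in phylo.clade_map.items()}
    missing = [sp for sp in out.index if sp not in clade_of]
    if missing:
        raise PaleoError(f"species missing from the tree's clade map: {missing[:10]}")
    out[level] = [clade_of[sp] for sp in out.index]
    out[f"{level}_age_ma"] = [ages[c] for c in out[level]]
    return out


def clade_age_model(
    traits: pd.DataFrame,
    phylo: Phylogeny,
    level: str = "family",
    mixed: bool = False,
    response: str = "sucrose_proportion",
) -> ModelFit:
    """Relate sucrose proportion to clade crown age.

    Plain fit: fractional-binomial GLM of the response on the crown age of
    each species' family (or order). ``mixed=True`` (family level only)
    keeps family age as the fixed effect and adds a random order intercept.
    """
    data = attach_clade_ages(traits, phylo, level)
    if mixed:
        if level != "family":
            raise GlmError("mixed clade-age model is defined for family age with order random")
        data = attach_clade_ages(data, phylo, "order")
        spec = ModelSpec(response, ["family_age_ma"], ["order"], "binomial")
        return fit_glmm(spec, data)
    age_col = f"{level}_age_ma"
    if np.ptp(data[age_col].to_numpy(dtype=float)) == 0:
        raise GlmError(f"{age_col} is constant: slope inestimable (rank deficiency)")
    return fit_glm(ModelSpec(response, [age_col], [], "binomial"), data)


def paleotemp_model(
    traits: pd.DataFrame,
    phylo: Phylogeny,
    series: TemperatureSeries,
    extra_predictors: list[str] | None = None,
    response: str = "sucrose_proportion",
) -> ModelFit:
    """GLMM of sucrose proportion on GMST at family origin.

    The temperature covariate is the linear interpolation of the series at
    each species' family crown age; random intercepts are family nested
    within order. ``extra_predictors`` (e.g. floral traits) enter as
    additional fixed effects.
    """
    data = attach_clade_ages(traits, phylo, "family")
    data = attach_clade_ages(data, phylo, "order")
    too_old = data[data["family_age_ma"] > series.max_age]
    if len(too_old):
        raise PaleoError(
            f"family crown ages beyond the series range: "
            f"{sorted(too_old['family'].unique())[:5]}"
        )
    data["paleotemp_c"] = interpolate_temperature(series, data["family_age_ma"].to_numpy())
    if np.ptp(data["paleotemp_c"].to_numpy()) == 0:
        raise GlmError("paleotemperature is constant: coefficient inestimable")
    predictors = ["paleotemp_c"] + list(extra_predictors or [])
    spec = ModelSpec(response, predictors, ["order", "family"], "binomial")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return fit_glmm(spec, data)
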