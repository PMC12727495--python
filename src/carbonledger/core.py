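"""Core data model and shared statistics for annual carbon-budget accounting.

The global carbon budget balances five annual fluxes, all in GtC yr⁻¹:
fossil emissions (E_FOS), net land-use-change emissions (E_LUC), the natural
land sink (S_LAND), the ocean sink (S_OCEAN) and the atmospheric growth rate
(G_ATM).  Mass conservation requires

    B_IM = E_FOS + E_LUC - S_LAND - S_OCEAN - G_ATM = 0,

and any nonzero budget imbalance B_IM measures how far the independent
component estimates fail to close.  This module provides the annual flux
series container, the imbalance identity, decadal averaging, ordinary
least-squares trends, quadrature error combination, the ppm <-> GtC unit
conversion and the airborne fraction.

Sign conventions are fixed throughout the package: sinks (S_LAND, S_OCEAN)
are positive when carbon is removed from the atmosphere, sources (E_FOS,
E_LUC) positive when carbon is added, and G_ATM is positive atmospheric
accumulation.  Corrections are applied as signed additions to stored values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BUDGET_COMPONENTS",
    "PPM_TO_GTC",
    "FluxSeries",
    "BudgetTable",
    "TrendResult",
    "EnsembleSeries",
    "budget_imbalance",
    "quadrature",
    "decadal_mean",
    "linear_trend",
    "ppm_gtc",
    "airborne_fraction",
]

#: The five balanced budget components, in identity order.
BUDGET_COMPONENTS = ("E_FOS", "E_LUC", "S_LAND", "S_OCEAN", "G_ATM")

#: Atmospheric mass-to-mixing-ratio constant, GtC per ppm CO2.
PPM_TO_GTC = 2.124


class AlignmentError(ValueError):
    """Raised when two series do not share a common year axis."""


@dataclass(frozen=True)
class FluxSeries:
    """One annual flux component with optional per-year 1-sigma uncertainty.

    Parameters
    ----------
    component
        Component label; one of :data:`BUDGET_COMPONENTS`, ``B_IM``, or a
        free-form tag for derived series.
    years
        Strictly ascending, contiguous calendar years (CE).
    values
        Annual flux in GtC yr⁻¹ (see module docstring for sign conventions).
    sigma
        Per-year 1-sigma uncertainty in GtC yr⁻¹; ``None`` when unknown.
        Missing uncertainty is treated as absent, never as zero.
    """

    component: str
    years: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or years.size == 0:
            raise ValueError("years must be a non-empty 1-D array")
        if values.shape != years.shape:
            raise ValueError("values and years must have equal length")
        if np.any(np.diff(years) != 1):
            raise ValueError("years must be strictly ascending and contiguous")
        if self.sigma is not None:
            sigma = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", sigma)
            if sigma.shape != years.shape:
                raise ValueError("sigma must match years in length")
            if np.any(sigma < 0):
                raise ValueError("sigma must be non-negative")

    def __len__(self) -> int:
        return self.years.size

    def window(self, first_year: int, last_year: int) -> "FluxSeries":
        """Return the sub-series covering ``[first_year, last_year]``."""
        if first_year < self.years[0] or last_year > self.years[-1]:
            raise ValueError(
                f"window {first_year}-{last_year} outside coverage "
                f"{self.years[0]}-{self.years[-1]}"
            )
        mask = (self.years >= first_year) & (self.years <= last_year)
        return FluxSeries(
            self.component,
            self.years[mask],
            self.values[mask],
            None if self.sigma is None else self.sigma[mask],
        )

    def with_values(self, values, sigma=None, component: str | None = None) -> "FluxSeries":
        return FluxSeries(
            component or self.component, self.years, np.asarray(values, float), sigma
        )

    def to_frame(self, member: str = "") -> pd.DataFrame:
        """Long-format frame: component, member, year, value, sigma."""
        return pd.DataFrame(
            {
                "component": self.component,
                "member": member,
                "year": self.years,
                "value_gtc_per_yr": self.values,
                "sigma_gtc_per_yr": np.nan if self.sigma is None else self.sigma,
            }
        )


def _check_aligned(series: Iterable[FluxSeries]) -> np.ndarray:
    series = list(series)
    years = series[0].years
    for s in series[1:]:
        if s.years.shape != years.shape or np.any(s.years != years):
            raise AlignmentError(
                f"year axes differ between {series[0].component} and {s.component}"
            )
    return years


@dataclass(frozen=True)
class BudgetTable:
    """The five budget components aligned on a common year axis."""

    e_fos: FluxSeries
    e_luc: FluxSeries
    s_land: FluxSeries
    s_ocean: FluxSeries
    g_atm: FluxSeries

    def __post_init__(self) -> None:
        _check_aligned(self.components.values())

    @property
    def components(self) -> dict[str, FluxSeries]:
        return {
            "E_FOS": self.e_fos,
            "E_LUC": self.e_luc,
            "S_LAND": self.s_land,
            "S_OCEAN": self.s_ocean,
            "G_ATM": self.g_atm,
        }

    @property
    def years(self) -> np.ndarray:
        return self.e_fos.years

    def replace_component(self, name: str, series: FluxSeries) -> "BudgetTable":
        key = {"E_FOS": "e_fos", "E_LUC": "e_luc", "S_LAND": "s_land",
               "S_OCEAN": "s_ocean", "G_ATM": "g_atm"}[name]
        return replace(self, **{key: series})

    @classmethod
    def from_values(
        cls,
        years,
        e_fos,
        e_luc,
        s_land,
        s_ocean,
        g_atm=None,
        sigmas: Mapping[str, Sequence[float]] | None = None,
    ) -> "BudgetTable":
        """Build a table from plain arrays.

        When ``g_atm`` is omitted it is set to close the budget exactly
        (B_IM identically zero), which is how synthetic truth tables are
        constructed.
        """
        years = np.asarray(years, int)
        sigmas = sigmas or {}

        def mk(name, vals):
            return FluxSeries(name, years, np.asarray(vals, float), sigmas.get(name))

        e_fos_s, e_luc_s = mk("E_FOS", e_fos), mk("E_LUC", e_luc)
        s_land_s, s_ocean_s = mk("S_LAND", s_land), mk("S_OCEAN", s_ocean)
        if g_atm is None:
            g_atm = (
                e_fos_s.values + e_luc_s.values - s_land_s.values - s_ocean_s.values
            )
        return cls(e_fos_s, e_luc_s, s_land_s, s_ocean_s, mk("G_ATM", g_atm))


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of an annual series, rescaled to GtC yr⁻¹ per decade."""

    slope: float
    slope_se: float
    p_value: float
    n_years: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.slope_se < 0:
            raise ValueError("slope_se must be non-negative")


@dataclass
class EnsembleSeries:
    """A named collection of member flux series sharing one component label.

    Member coverage may differ; statistics are computed per year over the
    members that cover it.
    """

    members: dict[str, FluxSeries] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = {s.component for s in self.members.values()}
        if len(labels) > 1:
            raise ValueError(f"members mix component labels: {sorted(labels)}")

    @property
    def component(self) -> str:
        return next(iter(self.members.values())).component

    def year_range(self) -> tuple[int, int]:
        lo = min(s.years[0] for s in self.members.values())
        hi = max(s.years[-1] for s in self.members.values())
        return lo, hi

    def mean_series(self, min_members: int = 1) -> FluxSeries:
        """Per-year unweighted mean over covering members.

        Years covered by fewer than ``min_members`` members are dropped from
        the ends; interior gaps are impossible because member series are
        contiguous, but mixed coverage can still produce a short axis.
        """
        lo, hi = self.year_range()
        years = np.arange(lo, hi + 1)
        stack = np.full((len(self.members), years.size), np.nan)
        for i, s in enumerate(self.members.values()):
            stack[i, s.years - lo] = s.values
        counts = np.sum(~np.isnan(stack), axis=0)
        keep = counts >= min_members
        # trim to the longest contiguous block satisfying the coverage rule
        idx = np.flatnonzero(keep)
        years, stack = years[idx[0]: idx[-1] + 1], stack[:, idx[0]: idx[-1] + 1]
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack, axis=0)
        n = np.sum(~np.isnan(stack), axis=0)
        sd = np.where(n > 1, np.nanstd(stack, axis=0, ddof=1), np.nan)
        sigma = sd if np.all(n > 1) else None
        return FluxSeries(self.component, years, mean, sigma)


# ---------------------------------------------------------------------------
# operations


def budget_imbalance(budget: BudgetTable) -> FluxSeries:
    """Per-year budget imbalance B_IM = E_FOS + E_LUC - S_LAND - S_OCEAN - G_ATM.

    The returned sigma is the quadrature of the five component sigmas when
    all are present, and absent otherwise.
    """
    c = budget.components
    values = (
        c["E_FOS"].values
        + c["E_LUC"].values
        - c["S_LAND"].values
        - c["S_OCEAN"].values
        - c["G_ATM"].values
    )
    sigma = None
    if all(s.sigma is not None for s in c.values()):
        sigma = np.sqrt(sum(s.sigma**2 for s in c.values()))
    return FluxSeries("B_IM", budget.years, values, sigma)


def quadrature(sigmas: Sequence[float]) -> float:
    """Combine independent 1-sigma uncertainties: sqrt(sum of squares)."""
    arr = np.asarray(sigmas, dtype=float)
    if np.any(arr < 0):
        raise ValueError("quadrature inputs must be non-negative")
    return float(np.sqrt(np.sum(arr**2)))


def decadal_mean(
    series: FluxSeries, first_year: int, last_year: int
) -> tuple[float, float | None]:
    """Mean flux over ``[first_year, last_year]`` with its 1-sigma.

    The returned sigma is the mean of the annual sigmas (uncertainty treated
    as systematic across years, matching how decadal budget uncertainties of
    the same magnitude as annual ones are reported), not sigma/sqrt(n).
    """
    win = series.window(first_year, last_year)
    mean = float(np.mean(win.values))
    sigma = None if win.sigma is None else float(np.mean(win.sigma))
    return mean, sigma


def linear_trend(series: FluxSeries) -> TrendResult:
    """OLS slope of flux against calendar year, reported per decade.

    A plain iid-error two-sided t-test is used on the slope; no
    autocorrelation correction is applied.
    """
    if len(series) < 3:
        raise ValueError("linear_trend needs at least 3 years")
    res = stats.linregress(series.years.astype(float), series.values)
    return TrendResult(
        slope=10.0 * res.slope,
        slope_se=10.0 * res.stderr,
        p_value=float(res.pvalue),
        n_years=len(series),
    )


def ppm_gtc(value, direction: str = "ppm_to_gtc", factor: float = PPM_TO_GTC):
    """Convert between atmospheric ppm CO2 and GtC.

    ``direction`` is ``"ppm_to_gtc"`` (multiply by ``factor``) or
    ``"gtc_to_ppm"`` (divide).  The default factor 2.124 GtC ppm⁻¹ is the
    conventional constant for the whole atmosphere.
    """
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    if direction == "ppm_to_gtc":
        return value * factor
    if direction == "gtc_to_ppm":
        return value / factor
    raise ValueError(f"unknown direction {direction!r}")


def airborne_fraction(budget: BudgetTable, denominator: str = "emissions") -> FluxSeries:
    """Annual airborne fraction AF_t.

    With ``denominator="emissions"`` (default) AF_t = G_ATM / (E_FOS + E_LUC):
    the fraction of that year's anthropogenic input remaining airborne.  The
    alternative ``"budget"`` uses G_ATM + S_LAND + S_OCEAN, which is identical
    under perfect closure but differs by B_IM otherwise.
    """
    c = budget.components
    if denominator == "emissions":
        denom = c["E_FOS"].values + c["E_LUC"].values
    elif denominator == "budget":
        denom = c["G_ATM"].values + c["S_LAND"].values + c["S_OCEAN"].values
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if np.any(denom <= 0):
        raise ValueError("airborne fraction undefined: non-positive denominator")
    return FluxSeries("AF", budget.years, c["G_ATM"].values / denom)
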