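"""Attribution of sink weakening to climate change and regional decomposition.

Land and ocean models are run twice under a common protocol: once with
observed CO2 and observed climate, and once with the same CO2 trajectory
but a constant (natural) climate.  The per-year difference of the two sink
series is the climate-change effect on that sink.  The convention here
stores the effect as positive weakening,

    S^clim_t = S(fixed climate)_t − S(full forcing)_t ,

so that its contribution to atmospheric growth is directly

    G_ATM^clim_t = AF_t × (S_LAND^clim_t + S_OCEAN^clim_t),

with AF the airborne fraction.  (Display layers that plot the effect as a
negative flux simply negate.)  Accumulating G_ATM^clim and dividing by the
ppm conversion factor yields the cumulative ppm of atmospheric CO2 increase
attributable to the carbon-climate feedback.

The regional decomposition splits each region's net land flux into a CO2-
fertilization sink, a climate-effect source and a land-use-change source,
with the net uncertainty the quadrature of the three component sigmas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PPM_TO_GTC, FluxSeries, quadrature

__all__ = [
    "ClimateEffect",
    "RegionalDecomposition",
    "climate_effect",
    "gatm_clim",
    "cumulative_ppm",
    "percent_reduction",
    "regional_decomposition",
]


@dataclass
class ClimateEffect:
    """Climate-change effect on the sinks and its atmospheric imprint."""

    years: np.ndarray
    s_land_clim: np.ndarray   # GtC yr⁻¹, positive = land sink weakened
    s_ocean_clim: np.ndarray  # GtC yr⁻¹, positive = ocean sink weakened
    g_atm_clim: np.ndarray    # GtC yr⁻¹ added to atmospheric growth
    cumulative_ppm: np.ndarray


@dataclass(frozen=True)
class RegionalDecomposition:
    """One region's decadal net land flux split into three drivers.

    Signs follow the attribution convention: the CO2-fertilization effect
    is a sink (positive), climate and land-use-change effects are sources
    (positive), and net = co2 − climate − luc.
    """

    region: str
    co2_effect: float
    climate_effect: float
    luc_effect: float
    co2_sigma: float = 0.0
    climate_sigma: float = 0.0
    luc_sigma: float = 0.0

    @property
    def net(self) -> float:
        return self.co2_effect - self.climate_effect - self.luc_effect

    @property
    def net_sigma(self) -> float:
        return quadrature([self.co2_sigma, self.climate_sigma, self.luc_sigma])


def climate_effect(
    full_run: FluxSeries, fixed_climate_run: FluxSeries
) -> FluxSeries:
    """Sink weakening due to climate: fixed-climate minus full-forcing run.

    Positive values mean climate change weakened the sink.
    """
    if full_run.years.shape != fixed_climate_run.years.shape or np.any(
        full_run.years != fixed_climate_run.years
    ):
        raise ValueError("paired runs must share one year axis")
    return FluxSeries(
        f"{full_run.component}_clim",
        full_run.years,
        fixed_climate_run.values - full_run.values,
    )


def gatm_clim(
    af: FluxSeries, land_eff: FluxSeries, ocean_eff: FluxSeries
) -> FluxSeries:
    """Atmospheric-growth contribution of the climate effect:
    G_ATM^clim_t = AF_t × (S_LAND^clim_t + S_OCEAN^clim_t)."""
    for s in (land_eff, ocean_eff):
        if s.years.shape != af.years.shape or np.any(s.years != af.years):
            raise ValueError("series must share one year axis")
    if np.any((af.values < 0) | (af.values > 1)):
        raise ValueError("airborne fraction must lie in [0, 1]")
    return FluxSeries(
        "G_ATM_clim", af.years, af.values * (land_eff.values + ocean_eff.values)
    )


def cumulative_ppm(
    gatm_clim_series: FluxSeries, factor: float = PPM_TO_GTC
) -> FluxSeries:
    """Running atmospheric-concentration contribution in ppm since the
    series' first year."""
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    return FluxSeries(
        "cumulative_ppm",
        gatm_clim_series.years,
        np.cumsum(gatm_clim_series.values) / factor,
    )


def percent_reduction(effect_decadal: float, sink_decadal: float) -> float:
    """Percentage sink reduction relative to the no-climate-change
    counterfactual: −100 × effect / (sink + effect)."""
    counterfactual = sink_decadal + effect_decadal
    if counterfactual <= 0:
        raise ValueError("counterfactual sink must be positive")
    return -100.0 * effect_decadal / counterfactual


def regional_decomposition(
    regions: list[RegionalDecomposition], check_global_tol: float | None = None
) -> list[RegionalDecomposition]:
    """Validate a list of regional decompositions and optionally append a
    global row (sum of regions; quadrature sigma across regions).

    ``check_global_tol`` given: a region named ``"Global"`` must already be
    present and must equal the sum of the others within the tolerance.
    """
    if check_global_tol is not None:
        named = {r.region: r for r in regions}
        if "Global" not in named:
            raise ValueError("no Global row to check")
        rest = [r for r in regions if r.region != "Global"]
        total = sum(r.net for r in rest)
        if abs(total - named["Global"].net) > check_global_tol:
            raise ValueError(
                f"regional nets sum to {total:.3f}, Global row is "
                f"{named['Global'].net:.3f}"
            )
    return regions
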