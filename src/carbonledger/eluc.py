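"""Transient-carbon-density (delta-L) correction of land-use-change emissions.

Bookkeeping models of land-use-change emissions (E_LUC) conventionally use
static, present-day equilibrium carbon densities for each land-cover type.
Because actual biomass and soil densities have grown with atmospheric CO2,
static densities understate the carbon at stake in recent deforestation and
hence the E_LUC trend.  The delta-L correction replaces static by transient
densities.  Models whose runs exist in both modes provide per-subcomponent
scaling ratios (transient/static); static-only models are corrected by
scaling each of their five E_LUC subcomponents — total deforestation, forest
(re-)growth, gross wood-harvest sources, gross wood-harvest sinks, and other
transitions — by the across-reference-model average ratio, then re-summing.

The ensemble delta-L and its uncertainty combine per-model uncertainties
with between-model spread through a DerSimonian–Laird random-effects model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import FluxSeries

__all__ = [
    "ELUC_SUBCOMPONENTS",
    "ElucComponents",
    "DeltaLResult",
    "component_ratios",
    "apply_transient_scaling",
    "delta_L",
    "dersimonian_laird",
]

#: The five gross E_LUC subcomponents; regrowth and harvest sinks are stored
#: as negative (uptake) fluxes so the net is their plain sum.
ELUC_SUBCOMPONENTS = (
    "deforestation",
    "regrowth",
    "harvest_src",
    "harvest_snk",
    "other",
)

#: Static-subcomponent fluxes smaller than this (GtC yr⁻¹) carry no ratio
#: information; the ratio falls back to 1 (no scaling).
RATIO_FALLBACK_THRESHOLD = 1e-6


@dataclass
class ElucComponents:
    """Per-year E_LUC subcomponent fluxes for one bookkeeping model."""

    model_id: str
    years: np.ndarray
    components: dict[str, np.ndarray]
    density_mode: str = "static"  # static | transient

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        if self.density_mode not in ("static", "transient"):
            raise ValueError("density_mode must be 'static' or 'transient'")
        missing = set(ELUC_SUBCOMPONENTS) - set(self.components)
        if missing:
            raise ValueError(f"missing subcomponents: {sorted(missing)}")
        for name in ELUC_SUBCOMPONENTS:
            arr = np.asarray(self.components[name], float)
            if arr.shape != self.years.shape:
                raise ValueError(f"component {name} length mismatch")
            self.components[name] = arr

    @property
    def net(self) -> FluxSeries:
        """Net E_LUC = sum of the five subcomponents."""
        total = sum(self.components[name] for name in ELUC_SUBCOMPONENTS)
        return FluxSeries("E_LUC", self.years, total)


@dataclass
class DeltaLResult:
    """Ensemble delta-L correction: annual mean, 1-sigma, and cumulative sum."""

    years: np.ndarray
    delta: np.ndarray          # GtC yr⁻¹, positive increases E_LUC
    sigma: np.ndarray          # GtC yr⁻¹
    cumulative: np.ndarray     # GtC since the first year
    per_model: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def series(self) -> FluxSeries:
        return FluxSeries("delta_L", self.years, self.delta, self.sigma)


def component_ratios(
    reference_pairs: list[tuple[ElucComponents, ElucComponents]],
) -> dict[str, np.ndarray]:
    """Per-subcomponent, per-year transient/static ratios, averaged across
    reference models.

    Each pair must come from the same model with aligned years.  Where a
    static subcomponent flux is ~0 the ratio is undefined and falls back to
    1 for that model before averaging.
    """
    if not reference_pairs:
        raise ValueError("at least one reference pair required")
    years = reference_pairs[0][0].years
    per_model = []
    for static, transient in reference_pairs:
        if static.model_id != transient.model_id:
            raise ValueError(
                f"pair mixes models {static.model_id!r}/{transient.model_id!r}"
            )
        if static.density_mode != "static" or transient.density_mode != "transient":
            raise ValueError("pair must be (static, transient)")
        if static.years.shape != years.shape or np.any(static.years != years) or np.any(
            transient.years != years
        ):
            raise ValueError("reference pairs must share one year axis")
        ratios = {}
        for name in ELUC_SUBCOMPONENTS:
            s = static.components[name]
            t = transient.components[name]
            safe = np.abs(s) >= RATIO_FALLBACK_THRESHOLD
            r = np.ones_like(s)
            r[safe] = t[safe] / s[safe]
            if not np.all(safe):
                warnings.warn(
                    f"{static.model_id}/{name}: ratio fallback to 1 in "
                    f"{int(np.sum(~safe))} year(s) with ~zero static flux",
                    stacklevel=2,
                )
            ratios[name] = r
        per_model.append(ratios)
    return {
        name: np.mean([m[name] for m in per_model], axis=0)
        for name in ELUC_SUBCOMPONENTS
    }


def apply_transient_scaling(
    target: ElucComponents, ratios: dict[str, np.ndarray]
) -> FluxSeries:
    """Scale a static-density model's subcomponents by the averaged ratios
    and sum to a net transient-density E_LUC estimate."""
    if target.density_mode != "static":
        raise ValueError("target must be a static-density run")
    missing = set(ELUC_SUBCOMPONENTS) - set(ratios)
    if missing:
        raise ValueError(f"missing ratios for: {sorted(missing)}")
    total = np.zeros_like(target.years, dtype=float)
    for name in ELUC_SUBCOMPONENTS:
        r = np.asarray(ratios[name], float)
        if r.shape != target.years.shape:
            raise ValueError(f"ratio for {name} does not match target years")
        total = total + target.components[name] * r
    return FluxSeries("E_LUC", target.years, total)


def dersimonian_laird(
    estimates: np.ndarray, variances: np.ndarray
) -> tuple[float, float]:
    """DerSimonian–Laird between-study variance tau² for one year.

    Returns ``(tau2, weighted_mean)`` using inverse-variance weights
    w_i = 1/s_i².  tau² is truncated at zero.
    """
    y = np.asarray(estimates, float)
    v = np.asarray(variances, float)
    k = y.size
    if k < 2:
        return 0.0, float(y[0])
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - ybar) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    return float(tau2), float(ybar)


def delta_L(
    per_model: dict[str, FluxSeries],
    base_year: int | None = None,
) -> DeltaLResult:
    """Combine per-model delta-L series into the ensemble correction.

    Each member series is one model's (transient − static) net E_LUC
    difference, with its per-year 1-sigma.  The annual ensemble delta-L is
    the unweighted cross-model mean.  Its 1-sigma combines the
    DerSimonian–Laird between-model variance tau² with the mean within-model
    variance:  sigma = sqrt(tau² + mean_i s_i²).

    Models with endogenous transient densities enter directly as their own
    precomputed difference series.
    """
    if not per_model:
        raise ValueError("no models supplied")
    series = list(per_model.values())
    years = series[0].years
    for s in series[1:]:
        if s.years.shape != years.shape or np.any(s.years != years):
            raise ValueError("per-model delta-L series must share one year axis")
    values = np.stack([s.values for s in series])
    if len(series) == 1:
        warnings.warn("single delta-L model: sigma taken from that model alone",
                      stacklevel=2)
        s0 = series[0]
        sigma = s0.sigma if s0.sigma is not None else np.zeros_like(s0.values)
        delta = s0.values.copy()
    else:
        if any(s.sigma is None for s in series):
            raise ValueError("every model needs a sigma series")
        variances = np.stack([s.sigma**2 for s in series])
        delta = values.mean(axis=0)
        sigma = np.empty_like(delta)
        for t in range(years.size):
            tau2, _ = dersimonian_laird(values[:, t], variances[:, t])
            sigma[t] = np.sqrt(tau2 + variances[:, t].mean())
    if base_year is None:
        base_year = int(years[0])
    cum = np.cumsum(np.where(years >= base_year, delta, 0.0))
    return DeltaLResult(
        years=years,
        delta=delta,
        sigma=sigma,
        cumulative=cum,
        per_model={k: v.values for k, v in per_model.items()},
    )
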