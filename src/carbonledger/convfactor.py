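"""Inversion-based ppm-to-GtC conversion-factor estimation.

The atmospheric growth rate G_ATM is observed as a mole-fraction increase
(ppm yr⁻¹) and converted to mass with a constant 2.124 GtC ppm⁻¹.  In
reality the factor varies from year to year because surface stations do not
instantaneously sample a well-mixed atmosphere.  Each atmospheric-inversion
member provides (a) its net annual carbon input to the atmosphere, fossil
emissions plus inverse-derived net land and ocean fluxes, in GtC yr⁻¹, and
(b) model-sampled station mole fractions from which an annual growth rate
in ppm yr⁻¹ is computed exactly as for the observations.  Their annual
ratio is that member's conversion factor; ensemble statistics over members
give its per-year spread and interannual variability, which propagate into
an uncertainty band on G_ATM and hence on the budget imbalance.  G_ATM
itself is left unadjusted; only its uncertainty band is produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import PPM_TO_GTC, FluxSeries

__all__ = [
    "InversionMember",
    "ConversionFactorSeries",
    "annual_growth_ppm",
    "member_conversion_factor",
    "ensemble_factor_stats",
    "gatm_uncertainty",
    "bim_band",
]

#: Annual growth rates smaller than this (ppm yr⁻¹) make the ratio unstable;
#: such years are flagged and excluded from ensemble statistics.
MIN_RELIABLE_GROWTH = 0.05


@dataclass
class InversionMember:
    """One atmospheric-inversion ensemble member.

    ``net_input`` is the per-year net atmospheric carbon input (GtC yr⁻¹)
    over ``years``.  Growth is supplied either directly (``growth_ppm``) or
    as a finer-than-annual mole-fraction record (``mf_time`` in decimal
    years with ``mf_ppm``) from which :func:`annual_growth_ppm` derives it.
    """

    member_id: str
    years: np.ndarray
    net_input: np.ndarray
    growth_ppm: np.ndarray | None = None
    mf_time: np.ndarray | None = None
    mf_ppm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.net_input = np.asarray(self.net_input, float)
        if self.net_input.shape != self.years.shape:
            raise ValueError("net_input must match years")
        if self.growth_ppm is None:
            if self.mf_time is None or self.mf_ppm is None:
                raise ValueError("need growth_ppm or a mole-fraction record")
            self.growth_ppm = annual_growth_ppm(
                np.asarray(self.mf_time, float),
                np.asarray(self.mf_ppm, float),
                self.years,
            )
        else:
            self.growth_ppm = np.asarray(self.growth_ppm, float)
            if self.growth_ppm.shape != self.years.shape:
                raise ValueError("growth_ppm must match years")


@dataclass
class ConversionFactorSeries:
    """Ensemble conversion-factor statistics (GtC ppm⁻¹)."""

    years: np.ndarray
    mean: np.ndarray                 # per-year ensemble mean factor
    sigma: np.ndarray                # per-year (n−1) spread across members
    n_members: np.ndarray            # members contributing per year
    interannual_sigma: float         # sd of the mean series over the window
    window: tuple[int, int]
    reference: float = PPM_TO_GTC
    per_member: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def mean_member_sigma(self) -> float:
        return float(np.mean(self.sigma))


def annual_growth_ppm(
    time: np.ndarray, ppm: np.ndarray, years: np.ndarray
) -> np.ndarray:
    """Annual CO2 growth rates from a sub-annual mole-fraction record.

    The record is deseasonalized by removing a fitted two-harmonic annual
    cycle (estimated jointly with a cubic long-term trend so the harmonics
    are not contaminated by curvature), and the deseasonalized series is
    interpolated to 1 January boundaries; the growth for year y is the
    boundary value at 1 Jan (y+1) minus at 1 Jan y.  ``time`` is in decimal
    years.

    This mirrors the boundary-difference convention used for the observed
    growth rate; the fitted-harmonic deseasonalization is an approximation
    to the operational curve-fitting procedures.
    """
    time = np.asarray(time, float)
    ppm = np.asarray(ppm, float)
    years = np.asarray(years, int)
    if time.ndim != 1 or time.shape != ppm.shape or time.size < 24:
        raise ValueError("need a 1-D sub-annual record of at least 24 samples")
    if time[0] > years[0] or time[-1] < years[-1] + 1:
        raise ValueError(
            f"record {time[0]:.2f}-{time[-1]:.2f} does not span requested "
            f"years {years[0]}-{years[-1] + 1}"
        )
    t0 = time.mean()
    tc = time - t0
    design = np.column_stack(
        [
            np.ones_like(tc), tc, tc**2, tc**3,
            np.cos(2 * np.pi * time), np.sin(2 * np.pi * time),
            np.cos(4 * np.pi * time), np.sin(4 * np.pi * time),
        ]
    )
    coef, *_ = np.linalg.lstsq(design, ppm, rcond=None)
    seasonal = design[:, 4:] @ coef[4:]
    deseason = ppm - seasonal
    boundaries = np.interp(np.arange(years[0], years[-1] + 2, dtype=float),
                           time, deseason)
    return np.diff(boundaries)


def member_conversion_factor(member: InversionMember) -> np.ndarray:
    """Per-year factor c_t = net input / growth for one member.

    Years with |growth| below :data:`MIN_RELIABLE_GROWTH` ppm yr⁻¹ are
    returned as NaN (flagged unreliable) rather than as huge ratios.
    """
    growth = member.growth_ppm
    unreliable = np.abs(growth) < MIN_RELIABLE_GROWTH
    if unreliable.any():
        warnings.warn(
            f"{member.member_id}: {int(unreliable.sum())} year(s) with "
            "near-zero growth excluded from factor estimation",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = member.net_input / growth
    return np.where(unreliable, np.nan, factors)


def ensemble_factor_stats(
    members: list[InversionMember], window: tuple[int, int]
) -> ConversionFactorSeries:
    """Per-year ensemble mean/spread of the conversion factor and its
    interannual variability over the analysis ``window``.

    Member coverage may differ; a year needs at least two covering members
    or it is dropped with a warning.
    """
    first, last = window
    years = np.arange(first, last + 1)
    table = np.full((len(members), years.size), np.nan)
    per_member = {}
    for i, m in enumerate(members):
        factors = member_conversion_factor(m)
        per_member[m.member_id] = factors
        mask = (m.years >= first) & (m.years <= last)
        table[i, m.years[mask] - first] = factors[mask]
    n = np.sum(~np.isnan(table), axis=0)
    keep = n >= 2
    if not keep.all():
        warnings.warn(
            f"{int(np.sum(~keep))} year(s) with <2 members dropped", stacklevel=2
        )
    years, table, n = years[keep], table[:, keep], n[keep]
    if years.size == 0:
        raise ValueError("no year has at least two covering members")
    mean = np.nanmean(table, axis=0)
    sigma = np.nanstd(table, axis=0, ddof=1)
    interannual = float(np.std(mean, ddof=1)) if years.size > 1 else 0.0
    return ConversionFactorSeries(
        years=years,
        mean=mean,
        sigma=sigma,
        n_members=n,
        interannual_sigma=interannual,
        window=(int(years[0]), int(years[-1])),
        per_member=per_member,
    )


def gatm_uncertainty(
    gatm: FluxSeries,
    growth_obs_sigma_ppm: float | np.ndarray,
    cf: ConversionFactorSeries,
) -> FluxSeries:
    """Per-year 1-sigma on G_ATM from conversion-factor uncertainty.

    Three sources enter as relative errors combined in quadrature, then
    scale G_ATM:

    1. the annual observational growth-rate uncertainty (relative to the
       observed growth, i.e. sigma_ppm × reference factor / G_ATM);
    2. the interannual variability of the ensemble-mean factor over the
       analysis window;
    3. the mean across-member spread of the factor over the window.

    All three must be supplied; there are no silent defaults.
    """
    sigma_ppm = np.broadcast_to(
        np.asarray(growth_obs_sigma_ppm, float), gatm.values.shape
    )
    if np.any(sigma_ppm < 0):
        raise ValueError("growth sigma must be non-negative")
    if cf.interannual_sigma is None or cf.sigma is None:
        raise ValueError("conversion-factor statistics incomplete")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_growth = np.where(
            gatm.values != 0, sigma_ppm * cf.reference / np.abs(gatm.values), 0.0
        )
    rel_interannual = cf.interannual_sigma / np.mean(cf.mean)
    rel_members = cf.mean_member_sigma / np.mean(cf.mean)
    rel_total = np.sqrt(rel_growth**2 + rel_interannual**2 + rel_members**2)
    return FluxSeries(
        "sigma_G_ATM", gatm.years, np.abs(gatm.values) * rel_total
    )


def bim_band(
    bim: FluxSeries, sigma_gatm: FluxSeries, k: float = 1.0
) -> "pd.DataFrame":
    """Flag years whose budget imbalance exceeds the G_ATM-derived band.

    A year is significant iff |B_IM| > k × sigma; years inside the band have
    an imbalance explicable by growth-rate conversion uncertainty alone.
    """
    import pandas as pd

    if bim.years.shape != sigma_gatm.years.shape or np.any(
        bim.years != sigma_gatm.years
    ):
        raise ValueError("year axes differ")
    sig = np.abs(bim.values) > k * sigma_gatm.values
    return pd.DataFrame(
        {
            "year": bim.years,
            "bim_gtc_per_yr": bim.values,
            "sigma_gtc_per_yr": sigma_gatm.values,
            "significant": sig,
        }
    )
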