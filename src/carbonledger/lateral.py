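"""Lateral-carbon-export (LCE) correction of the land sink.

Rivers, lakes and reservoirs export carbon from terrestrial ecosystems to
sediments and the ocean.  Budget accounting uses a natural (pre-industrial)
export estimate but has historically neglected its anthropogenic
perturbation.  The perturbation of the land-to-inland-water flux, F'_LI, is
partitioned into added aquatic CO2 evasion (F'_IA), added burial in aquatic
sediments (F'_IS) and added export to the open ocean (F'_IE):

    F'_LI = F'_IA + F'_IS + F'_IE .

By origin, F'_LI splits into displaced dissolved soil CO2 (a lateral
relocation of respired CO2 with no effect on the land sink) and terrestrial
organic carbon.  Of the organic share, the part that is decomposed in
inland waters and evades as CO2 — organic share minus burial minus ocean
export — is a genuine reduction of S_LAND.  No correction is applied to the
ocean sink: exported carbon is assumed to stay in the ocean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FluxSeries, quadrature

__all__ = [
    "LateralFluxPerturbation",
    "PartitionCheck",
    "validate_partition",
    "sland_lce_correction",
    "apply_lce",
]

#: Residual tolerance matching one-half of the last printed digit (GtC yr⁻¹).
DEFAULT_PARTITION_TOL = 0.005


@dataclass(frozen=True)
class LateralFluxPerturbation:
    """Anthropogenic lateral-flux perturbation (decadal mean, GtC yr⁻¹).

    All fields are non-negative decadal-mean fluxes; ``*_sigma`` are their
    1-sigma uncertainties as assessed in the source studies.  The default
    values are the 2014–2023 anthropogenic perturbation relative to
    pre-industrial conditions.
    """

    f_li: float = 0.54
    f_ia: float = 0.34
    f_is: float = 0.09
    f_ie: float = 0.11
    dissolved_share: float = 0.27
    organic_share: float = 0.27
    f_li_sigma: float = 0.44
    f_ia_sigma: float = 0.26
    f_is_sigma: float = 0.03
    f_ie_sigma: float = 0.08
    correction_sigma: float = 0.06

    def __post_init__(self) -> None:
        for name in ("f_li", "f_ia", "f_is", "f_ie",
                     "dissolved_share", "organic_share"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PartitionCheck:
    ok: bool
    residual_partition: float   # F_LI − (F_IA + F_IS + F_IE)
    residual_origin: float      # F_LI − (dissolved + organic)
    failed: tuple[str, ...] = ()


def validate_partition(
    p: LateralFluxPerturbation, tol: float = DEFAULT_PARTITION_TOL
) -> PartitionCheck:
    """Check both conservation identities of the lateral-flux partition.

    Identity 1 (fate):   F_LI = F_IA + F_IS + F_IE
    Identity 2 (origin): F_LI = dissolved share + organic share
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    r_part = p.f_li - (p.f_ia + p.f_is + p.f_ie)
    r_orig = p.f_li - (p.dissolved_share + p.organic_share)
    failed = []
    if abs(r_part) > tol:
        failed.append("fate partition F_LI = F_IA + F_IS + F_IE")
    if abs(r_orig) > tol:
        failed.append("origin split F_LI = dissolved + organic")
    return PartitionCheck(
        ok=not failed,
        residual_partition=r_part,
        residual_origin=r_orig,
        failed=tuple(failed),
    )


def sland_lce_correction(
    p: LateralFluxPerturbation, tol: float = DEFAULT_PARTITION_TOL
) -> tuple[float, float]:
    """Land-sink reduction from enhanced lateral export, as (value, sigma).

    correction = organic share − F_IS − F_IE: the organic-origin carbon that
    is decomposed in inland waters and returned to the atmosphere.  Returned
    positive; it is applied as a reduction of S_LAND.  The dissolved share
    is lateral displacement of soil-respired CO2 and never enters.
    """
    check = validate_partition(p, tol)
    if not check.ok:
        raise ValueError(f"invalid partition: {'; '.join(check.failed)}")
    value = p.organic_share - p.f_is - p.f_ie
    if value < -tol:
        raise ValueError(
            "inconsistent partition: organic share smaller than burial + export"
        )
    return max(value, 0.0), p.correction_sigma


def apply_lce(
    sland: FluxSeries,
    correction: float,
    sigma: float = 0.0,
    ramp: np.ndarray | None = None,
) -> FluxSeries:
    """Apply the scalar decadal LCE correction as an annual reduction.

    ``ramp`` is a per-year weight in [0, 1] describing the historical growth
    of the anthropogenic perturbation (1 = full present-day amplitude); by
    default the full correction applies to every year.  Output sigma
    combines the input sigma with ramp × sigma in quadrature.
    """
    if ramp is None:
        ramp = np.ones(len(sland))
    ramp = np.asarray(ramp, float)
    if ramp.shape != sland.years.shape:
        raise ValueError("ramp length must match series")
    if np.any((ramp < 0) | (ramp > 1)):
        raise ValueError("ramp weights must lie in [0, 1]")
    values = sland.values - correction * ramp
    if sland.sigma is not None:
        out_sigma = np.array(
            [quadrature([s, sigma * r]) for s, r in zip(sland.sigma, ramp)]
        )
    elif sigma > 0:
        out_sigma = sigma * ramp
    else:
        out_sigma = None
    return FluxSeries(sland.component, sland.years, values, out_sigma)


def linear_ramp(years: np.ndarray, start: int | None = None, end: int | None = None) -> np.ndarray:
    """Weights growing linearly from 0 at ``start`` to 1 at ``end``.

    Minimal assumption for a perturbation known only as a present-day
    decadal mean relative to a pre-industrial baseline.
    """
    years = np.asarray(years, int)
    start = years[0] if start is None else start
    end = years[-1] if end is None else end
    if end <= start:
        raise ValueError("end must exceed start")
    return np.clip((years - start) / (end - start), 0.0, 1.0)
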