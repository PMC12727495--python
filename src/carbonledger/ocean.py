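"""Ocean-sink bias corrections and the two-stream S_OCEAN combination.

The ocean sink is assessed as the mean of two independent streams: an
ensemble of global ocean biogeochemical models (GOBMs) and an ensemble of
observation-based surface-CO2 flux products (fCO2 products).  Both carry
known, sign-certain biases:

* GOBMs underestimate the sink by about 10% (weak overturning, interior
  constraints, spin-up artefacts), corrected by a multiplicative upward
  scaling;
* fCO2 products ignore the cool-skin temperature gradient at the air-sea
  interface (which strengthens uptake) and the warm-layer gradient between
  measurement depth and the surface (which weakens it); their net effect is
  an additive upward adjustment.

Uncertainties on both corrections are calibrated from stated confidences
that the correction is positive: a correction c with confidence p that
c > 0 implies sigma = c / |Phi^-1(1-p)| for a normal error model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import FluxSeries, quadrature

__all__ = [
    "OceanCorrectionSpec",
    "scale_gobm",
    "skin_adjust",
    "confidence_sigma",
    "combine_ocean",
    "combined_correction_sigma",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OceanCorrectionSpec:
    """Parameters of the two ocean-sink corrections.

    ``gobm_scale_fraction`` is the multiplicative upward scaling of the GOBM
    ensemble (0.10 = +10%) with ``gobm_sigma_fraction`` its 1-sigma;
    ``cool_skin`` and ``warm_layer`` are the opposing additive temperature-
    gradient effects on the fCO2-product stream in GtC yr⁻¹ (cool skin
    increases the sink, warm layer decreases it) and ``fco2_sigma`` the
    1-sigma of their net.  The ``p_positive_*`` confidences are what the
    sigmas were calibrated from.
    """

    gobm_scale_fraction: float = 0.10
    gobm_sigma_fraction: float = 0.08
    cool_skin: float = 0.42
    warm_layer: float = 0.24
    fco2_sigma: float = 0.4
    p_positive_gobm: float = 0.90
    p_positive_fco2: float = 0.66

    def __post_init__(self) -> None:
        if self.cool_skin < 0 or self.warm_layer < 0:
            raise ValueError("skin/warm-layer magnitudes must be non-negative")
        for p in (self.p_positive_gobm, self.p_positive_fco2):
            if not 0.0 < p < 1.0:
                raise ValueError("confidences must lie in (0, 1)")


def scale_gobm(
    gobm: FluxSeries, spec: OceanCorrectionSpec
) -> tuple[FluxSeries, FluxSeries]:
    """Upward-scale the GOBM ensemble sink; returns (corrected, correction).

    corrected_t = gobm_t × (1 + f); the correction series carries
    sigma_t = gobm_t × sigma_f so its relative uncertainty is constant.
    """
    if spec.gobm_scale_fraction < 0:
        raise ValueError("scale fraction must be non-negative")
    f = spec.gobm_scale_fraction
    correction = FluxSeries(
        "S_OCEAN_gobm_correction",
        gobm.years,
        gobm.values * f,
        np.abs(gobm.values) * spec.gobm_sigma_fraction,
    )
    corrected = FluxSeries(
        gobm.component, gobm.years, gobm.values * (1.0 + f), gobm.sigma
    )
    return corrected, correction


def skin_adjust(
    fco2: FluxSeries, spec: OceanCorrectionSpec
) -> tuple[FluxSeries, tuple[float, float]]:
    """Apply the net cool-skin minus warm-layer adjustment to the
    fCO2-product stream; returns (corrected, (adjustment, sigma)).

    The adjustment is time-constant: the underlying field estimate is a
    single-period number.
    """
    net = spec.cool_skin - spec.warm_layer
    if net < 0:
        logger.warning(
            "net skin adjustment is negative (%.3f GtC/yr); the assessed "
            "confidence expects a positive correction", net
        )
    corrected = FluxSeries(fco2.component, fco2.years, fco2.values + net, fco2.sigma)
    return corrected, (net, spec.fco2_sigma)


def confidence_sigma(correction: float, p_positive: float) -> tuple[float, float]:
    """Sigma implied by a stated confidence that a correction is positive.

    For a normal error model N(correction, sigma), P(X > 0) = p_positive
    gives Z = Phi^-1(1 − p_positive) (negative for p > 0.5) and
    sigma = correction / |Z|.  Returns ``(sigma, z)``.
    """
    if correction <= 0:
        raise ValueError("correction must be positive")
    if p_positive <= 0.5:
        raise ValueError("confidence must exceed 0.5 (sign must be favoured)")
    if p_positive >= 1.0:
        raise ValueError("confidence must be below 1")
    z = float(stats.norm.ppf(1.0 - p_positive))
    return correction / abs(z), z


def combine_ocean(
    gobm_corrected: FluxSeries, fco2_corrected: FluxSeries
) -> FluxSeries:
    """Per-year unweighted mean of the two corrected ocean-sink streams.

    When both streams carry sigmas, the combined sigma is half the
    quadrature of the two (the variance rule for the mean of two
    independent estimates).
    """
    if gobm_corrected.years.shape != fco2_corrected.years.shape or np.any(
        gobm_corrected.years != fco2_corrected.years
    ):
        raise ValueError("year axes differ between ocean streams")
    values = 0.5 * (gobm_corrected.values + fco2_corrected.values)
    sigma = None
    if gobm_corrected.sigma is not None and fco2_corrected.sigma is not None:
        sigma = 0.5 * np.sqrt(gobm_corrected.sigma**2 + fco2_corrected.sigma**2)
    return FluxSeries("S_OCEAN", gobm_corrected.years, values, sigma)


def combined_correction_sigma(sigma_gobm: float, sigma_fco2: float) -> float:
    """1-sigma of the mean of the two independent corrections:
    half the quadrature of the stream sigmas."""
    return 0.5 * quadrature([sigma_gobm, sigma_fco2])
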