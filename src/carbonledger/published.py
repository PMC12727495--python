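"""Published worked-example inputs: assessed global decadal values.

These constants are fixed inputs for worked examples and desk checks, not
fitted quantities: the GCB2024 global budget averaged over 2014–2023, the
decadal flux corrections assessed from recent process evidence, and the
ensemble-stream means the ocean corrections act on.  All fluxes in
GtC yr⁻¹; uncertainties are 1 s.d.
"""

from __future__ import annotations

from .lateral import LateralFluxPerturbation
from .ocean import OceanCorrectionSpec

DECADE = (2014, 2023)

#: GCB2024 decadal-mean budget, (value, 1-sigma) per component.
GCB2024_DECADAL = {
    "E_FOS": (9.7, 0.5),
    "E_LUC": (1.1, 0.7),
    "S_LAND": (3.2, 0.9),
    "S_OCEAN": (2.9, 0.4),
    "G_ATM": (5.2, 0.02),
}

#: Decadal-mean corrections, signed per the sink-positive convention:
#: (component, value added to the component, 1-sigma).
DELTA_L_CORRECTION = ("E_LUC", +0.11, 0.04)     # transient carbon densities
RSS_CORRECTION = ("S_LAND", -0.5, 0.3)          # replaced sinks and sources
LCE_CORRECTION = ("S_LAND", -0.07, 0.06)        # lateral carbon export

#: Ocean ensemble-stream decadal means before correction.
GOBM_DECADAL = (2.6, 0.4)
FCO2_DECADAL = (3.1, 0.3)

#: Scalar parameters of the ocean corrections.
OCEAN_SPEC = OceanCorrectionSpec()

#: Anthropogenic lateral-flux perturbation and partition.
LATERAL_PERTURBATION = LateralFluxPerturbation()

#: Climate-change sink weakening over 2014–2023 (value, 1-sigma), applied
#: to the consolidated sinks.
CLIMATE_EFFECT_LAND = (0.8, 0.9)
CLIMATE_EFFECT_OCEAN = (0.18, 0.1)

#: Global land-flux decomposition over 2014–2023: CO2-fertilization sink,
#: climate-effect source, land-use-change source, each (value, 1-sigma).
GLOBAL_DECOMPOSITION = {
    "co2": (3.6, 1.0),
    "climate": (0.9, 0.6),
    "luc": (1.2, 0.7),
}
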