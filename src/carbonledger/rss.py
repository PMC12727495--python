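"""Replaced-sinks-and-sources (RSS) correction of the land sink.

The natural land sink S_LAND is conventionally estimated from vegetation
model runs that hold land cover at pre-industrial levels while CO2 and
climate vary ("S2" runs).  Because forest area has shrunk substantially
since pre-industrial times and forests take up more carbon per unit area
than the ecosystems that replaced them, the fixed-cover setup overestimates
the sink.  The correction reconstructs what the sink would be under the
actual, transient land cover by recombining per-plant-functional-type (PFT)
net biome production densities from the fixed-cover run with the transient
cover fractions of a companion land-use run ("S3"), and reports the bias

    bias_t = S_LAND(S2)_t − S_LAND(reconstructed)_t ,

positive when the fixed-cover run overestimates the sink.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import FluxSeries

__all__ = [
    "PftGrid",
    "PftFluxGrid",
    "RssResult",
    "reconstruct_sland",
    "rss_bias",
    "aggregate_rss",
]


@dataclass
class PftGrid:
    """Per-cell, per-PFT, per-year land-cover fractions.

    ``cover`` has shape (n_cells, n_pfts, n_years); fractions are in [0, 1]
    and sum to at most 1 per cell-year (any residual is bare ground,
    contributing zero flux).  ``areas`` are explicit cell areas in arbitrary
    but consistent units.
    """

    cell_ids: list[str]
    areas: np.ndarray
    pfts: list[str]
    years: np.ndarray
    cover: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, float)
        self.years = np.asarray(self.years, int)
        self.cover = np.asarray(self.cover, float)
        expected = (len(self.cell_ids), len(self.pfts), self.years.size)
        if self.cover.shape != expected:
            raise ValueError(f"cover shape {self.cover.shape} != {expected}")
        if np.any(self.cover < 0):
            raise ValueError("cover fractions must be non-negative")
        if np.any(self.cover.sum(axis=1) > 1 + 1e-9):
            raise ValueError("cover fractions exceed 1 in some cell-year")


@dataclass
class PftFluxGrid:
    """Per-cell, per-PFT, per-year net biome production density.

    Densities are in GtC yr⁻¹ per unit PFT area (sink positive), so a flux
    is density × cover fraction × cell area.  PFTs absent from the flux set
    (e.g. anthropogenic types only present in the transient-cover run) are
    marked NaN.
    """

    cell_ids: list[str]
    pfts: list[str]
    years: np.ndarray
    nbp: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.nbp = np.asarray(self.nbp, float)
        expected = (len(self.cell_ids), len(self.pfts), self.years.size)
        if self.nbp.shape != expected:
            raise ValueError(f"nbp shape {self.nbp.shape} != {expected}")


@dataclass
class RssResult:
    """Ensemble RSS bias: member series, mean, inter-model sigma, cumulative."""

    years: np.ndarray
    per_model: dict[str, np.ndarray]
    mean: np.ndarray
    sigma: np.ndarray | None
    cumulative: np.ndarray

    @property
    def series(self) -> FluxSeries:
        return FluxSeries("RSS", self.years, self.mean, self.sigma)


def _match(flux: PftFluxGrid, cover: PftGrid) -> None:
    if flux.cell_ids != cover.cell_ids:
        raise ValueError("cell sets differ between flux and cover grids")
    if flux.pfts != cover.pfts:
        raise ValueError("PFT sets differ between flux and cover grids")
    if flux.years.shape != cover.years.shape or np.any(flux.years != cover.years):
        raise ValueError("year axes differ between flux and cover grids")


def reconstruct_sland(
    nbp_s2: PftFluxGrid,
    cover_s3: PftGrid,
    missing_pft: str = "proxy",
) -> FluxSeries:
    """Global land sink under transient cover from fixed-cover NBP densities.

    S_t = sum over cells and PFTs of nbp_s2 × cover_s3 × cell area.

    PFTs with NaN density (present in the transient cover but never
    simulated under fixed cover) are handled per ``missing_pft``:

    - ``"proxy"``: use the cell-year's cover-weighted mean density over the
      PFTs that do have one (avoids silently dropping area);
    - ``"exclude"``: contribute zero flux.
    """
    _match(nbp_s2, cover_s3)
    nbp = nbp_s2.nbp.copy()
    # a missing density only matters where the transient cover puts area on it
    missing = np.isnan(nbp)
    nbp[missing & (cover_s3.cover == 0)] = 0.0
    missing = np.isnan(nbp)
    if missing.any():
        if missing_pft == "proxy":
            w = np.where(missing, 0.0, cover_s3.cover)
            wsum = w.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                proxy = np.where(
                    wsum > 0,
                    np.nansum(np.where(missing, 0.0, nbp) * w, axis=1, keepdims=True)
                    / wsum,
                    0.0,
                )
            nbp = np.where(missing, proxy, nbp)
            warnings.warn(
                f"{int(missing.sum())} missing PFT density value(s) filled with "
                "cover-weighted cell means",
                stacklevel=2,
            )
        elif missing_pft == "exclude":
            nbp = np.where(missing, 0.0, nbp)
            warnings.warn(
                f"{int(missing.sum())} missing PFT density value(s) excluded",
                stacklevel=2,
            )
        else:
            raise ValueError(f"unknown missing_pft mode {missing_pft!r}")
    flux = np.einsum("cpt,cpt,c->t", nbp, cover_s3.cover, cover_s3.areas)
    return FluxSeries("S_LAND", cover_s3.years, flux)


def rss_bias(sland_s2: FluxSeries, sland_corrected: FluxSeries) -> FluxSeries:
    """Fixed-cover sink minus transient-cover reconstruction; positive when
    the fixed-cover run overestimates the sink."""
    if sland_s2.years.shape != sland_corrected.years.shape or np.any(
        sland_s2.years != sland_corrected.years
    ):
        raise ValueError("year axes differ")
    return FluxSeries(
        "RSS", sland_s2.years, sland_s2.values - sland_corrected.values
    )


def aggregate_rss(members: dict[str, FluxSeries], base_year: int | None = None) -> RssResult:
    """Unweighted ensemble mean bias with inter-model (n−1) standard
    deviation and the cumulative bias since ``base_year``."""
    if not members:
        raise ValueError("no members supplied")
    series = list(members.values())
    years = series[0].years
    for s in series[1:]:
        if s.years.shape != years.shape or np.any(s.years != years):
            raise ValueError("member bias series must share one year axis")
    stack = np.stack([s.values for s in series])
    mean = stack.mean(axis=0)
    if len(series) >= 2:
        sigma = stack.std(axis=0, ddof=1)
    else:
        warnings.warn("single member: inter-model sigma undefined", stacklevel=2)
        sigma = None
    if base_year is None:
        base_year = int(years[0])
    cum = np.cumsum(np.where(years >= base_year, mean, 0.0))
    return RssResult(
        years=years,
        per_model={k: v.values for k, v in members.items()},
        mean=mean,
        sigma=sigma,
        cumulative=cum,
    )
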