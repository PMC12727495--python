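"""Synthetic-world generator with known truth and exact mass balance.

Every input the consolidation pipeline consumes can be generated here with
a known underlying truth: a budget table that closes exactly (B_IM = 0 each
year), biased ensemble "observations" of each component, per-PFT cover and
flux grids for the replaced-sinks-and-sources correction, bookkeeping
subcomponent tables for the transient-density correction, inversion members
consistent with a known conversion-factor series, and paired full/fixed-
climate sink runs with a known weakening trajectory.

The generator emulates the statistical structure of the real ensembles —
smooth trends, AR(1) interannual variability, inter-member spread, and the
documented biases at their assessed magnitudes — but none of the underlying
physics: no geography, no seasonality in fluxes, no process-based land or
ocean dynamics.  Its purpose is to give every pipeline stage a recoverable
truth, not realism.

Default magnitudes are chosen so the 2014–2023 decadal means of the truth
and of each bias match the assessed global values (fossil emissions near
9.7 GtC yr⁻¹, consolidated land sink near 2.7, ocean sink near 3.1,
transient-density correction near +0.11, cover-change bias near 0.5, ocean
model low bias 10%, skin-temperature deficit 0.18 GtC yr⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BudgetTable, EnsembleSeries, FluxSeries, PPM_TO_GTC
from .convfactor import InversionMember
from .eluc import ELUC_SUBCOMPONENTS, ElucComponents
from .lateral import LateralFluxPerturbation, linear_ramp
from .rss import PftFluxGrid, PftGrid

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "DensityModel",
    "TransitionEvent",
    "co2_trajectory",
    "simulate_world",
    "toy_bookkeeping",
    "make_pft_world",
]

#: Pre-industrial CO2 mixing ratio used as the density-model baseline (ppm).
CO2_PREINDUSTRIAL = 277.0


def co2_trajectory(years) -> np.ndarray:
    """Smooth exponential-plus-baseline CO2 trajectory (ppm).

    Anchored at 316 ppm in 1960 and 423 ppm in 2024 over a pre-industrial
    baseline of 277 ppm; the in-between shape is a plain exponential.
    """
    years = np.asarray(years, float)
    k = np.log(146.0 / 39.0) / 64.0          # fixes the two anchors
    a = 39.0 / np.exp(k * 260.0)
    return CO2_PREINDUSTRIAL + a * np.exp(k * (years - 1700.0))


@dataclass
class WorldConfig:
    """Knobs of the synthetic world.  Same seed ⇒ bit-identical outputs."""

    seed: int = 0
    first_year: int = 1960
    last_year: int = 2023

    # interannual variability: AR(1) with lag-1 correlation phi and
    # component-specific innovation sigma (GtC yr⁻¹), land largest
    ar1_phi: float = 0.5
    sigma_efos: float = 0.05
    sigma_eluc: float = 0.10
    sigma_sland: float = 0.50
    sigma_socean: float = 0.20

    # ensemble sizes
    n_bookkeeping: int = 4          # first two provide static+transient pairs
    n_dgvm: int = 7
    n_gobm: int = 10
    n_fco2: int = 10
    n_inversions: int = 14

    # inter-member spread (AR(1) innovation sigma per member, GtC yr⁻¹)
    bookkeeping_level_sd: float = 0.10   # relative level offset per model
    spread_bookkeeping: float = 0.06
    spread_dgvm: float = 0.30
    spread_gobm: float = 0.15
    spread_fco2: float = 0.15
    spread_inversion: float = 0.10

    # bias knobs, at assessed global magnitudes
    gobm_bias_fraction: float = 0.10     # GOBMs low by truth/(1+f)
    skin_deficit: float = 0.18           # fCO2 products low by this constant
    density_beta: float = 0.25           # transient density = static×(1+β ln CO2/CO2_1700)
    rss_slope: float = 0.54              # cover-change bias reaches this × x(t)
    rss_member_sd: float = 0.30          # inter-model spread of the bias slope
    delta_l_model_sigma: float = 0.03    # within-model delta-L 1σ (GtC yr⁻¹)

    # climate-weakening trajectories: w(t) = amp × x(t)^power
    clim_land_amp: float = 0.88
    clim_land_power: float = 1.2
    clim_ocean_amp: float = 0.27
    clim_ocean_power: float = 6.0
    clim_member_sd: float = 0.35         # relative spread of the weakening

    # conversion-factor structure
    cf_reference: float = PPM_TO_GTC
    cf_interannual_sd: float = 0.02      # relative interannual factor wobble
    cf_member_sd: float = 0.015          # relative member factor error
    seasonal_amp_ppm: float = 3.0

    lateral: LateralFluxPerturbation = field(default_factory=LateralFluxPerturbation)

    def __post_init__(self) -> None:
        if self.last_year <= self.first_year:
            raise ValueError("last_year must exceed first_year")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in [0, 1)")
        for name in ("gobm_bias_fraction", "skin_deficit", "rss_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def x(self) -> np.ndarray:
        """Normalized time in [0, 1] across the simulated span."""
        years = self.years
        return (years - years[0]) / (years[-1] - years[0])


@dataclass
class SyntheticWorld:
    """Everything the pipeline needs, plus the underlying truth."""

    config: WorldConfig
    truth: BudgetTable                       # closes exactly, B_IM ≡ 0
    co2_ppm: np.ndarray
    baseline: BudgetTable                    # biased, pre-consolidation table

    # land-use-change emissions
    bookkeeping_static: list[ElucComponents]
    bookkeeping_transient: list[ElucComponents]   # first two models only
    delta_l_true: np.ndarray
    delta_l_sigma: float

    # land sink / RSS
    dgvm_s2: dict[str, FluxSeries]
    pft_worlds: dict[str, tuple[PftFluxGrid, PftGrid, PftGrid]]  # (nbp, s2, s3)
    rss_true: np.ndarray
    rss_member_true: dict[str, np.ndarray]
    lce_true: np.ndarray
    lce_ramp: np.ndarray

    # ocean sink
    gobm: EnsembleSeries
    fco2: EnsembleSeries

    # growth rate / conversion factor
    inversions: list[InversionMember]
    cf_true: np.ndarray

    # climate attribution
    land_pairs: dict[str, tuple[FluxSeries, FluxSeries]]   # (full, fixed)
    ocean_pairs: dict[str, tuple[FluxSeries, FluxSeries]]
    clim_land_true: np.ndarray
    clim_ocean_true: np.ndarray


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) noise with lag-1 correlation phi and innovation sigma."""
    if sigma == 0:
        return np.zeros(n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - phi**2) if phi else sigma)
    eps = rng.normal(0.0, sigma, n - 1)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t - 1]
    return out


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent generator streams so changing one knob never reshuffles
    noise in an unrelated ensemble."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# toy bookkeeping model


@dataclass(frozen=True)
class DensityModel:
    """Equilibrium carbon density of a land-cover type (GtC per area unit).

    ``static`` uses the fixed value; ``transient`` scales it by
    (1 + beta × ln(CO2_t / CO2_preindustrial)), mimicking environmental
    density growth.
    """

    density: float
    mode: str = "static"            # static | transient
    beta: float = 0.25

    def at(self, years: np.ndarray, co2_ppm: np.ndarray | None = None) -> np.ndarray:
        years = np.asarray(years, float)
        if self.mode == "static":
            return np.full(years.shape, self.density)
        co2 = co2_trajectory(years) if co2_ppm is None else np.asarray(co2_ppm, float)
        return self.density * (1.0 + self.beta * np.log(co2 / CO2_PREINDUSTRIAL))


@dataclass(frozen=True)
class TransitionEvent:
    """One land-cover transition acted on by the toy bookkeeping model.

    ``kind`` is ``clearing`` (committed emission of the standing stock over
    ``tau`` years), ``regrowth`` (committed uptake toward the equilibrium
    density over ``tau``) or ``harvest`` (paired source over ``tau`` and
    regrowth sink over ``tau_sink`` on ``harvest_fraction`` of the stock).
    """

    year: int
    kind: str
    area: float
    tau: float = 20.0
    tau_sink: float = 40.0
    harvest_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in ("clearing", "regrowth", "harvest"):
            raise ValueError(f"unknown transition kind {self.kind!r}")
        if self.area < 0:
            raise ValueError("area must be non-negative")


def _committed(stock: float, event_year: int, tau: float, years: np.ndarray) -> np.ndarray:
    """Exponential committed-flux profile: year-n flux (n ≥ 1 after the
    event) is stock × (e^{−(n−1)/τ} − e^{−n/τ})."""
    n = years - event_year          # event year itself is n=1
    n = np.where(years >= event_year, n + 1, 0)
    out = np.zeros(years.size)
    active = n >= 1
    out[active] = stock * (
        np.exp(-(n[active] - 1) / tau) - np.exp(-n[active] / tau)
    )
    return out


def toy_bookkeeping(
    schedule: list[TransitionEvent],
    density: DensityModel,
    years: np.ndarray,
    available_area: float = np.inf,
) -> ElucComponents:
    """Run the cohort bookkeeping model over a transition schedule.

    Clearing emits the standing stock (area × density at the transition
    year) as an exponentially decaying committed source; regrowth takes up
    the same committed profile toward the equilibrium density as a sink;
    harvest splits into a decay source and a regrowth sink on a fraction of
    the stock.  Components are reported separately; regrowth and harvest
    sinks are negative.
    """
    years = np.asarray(years, int)
    cleared = sum(e.area for e in schedule if e.kind == "clearing")
    if cleared > available_area:
        raise ValueError("transition schedule over-allocates the available area")
    comps = {name: np.zeros(years.size) for name in ELUC_SUBCOMPONENTS}
    dens = density.at(years)
    for ev in schedule:
        d_at = density.at(np.array([ev.year]))[0]
        if ev.kind == "clearing":
            comps["deforestation"] += _committed(ev.area * d_at, ev.year, ev.tau, years)
        elif ev.kind == "regrowth":
            comps["regrowth"] -= _committed(ev.area * d_at, ev.year, ev.tau, years)
        else:
            stock = ev.area * d_at * ev.harvest_fraction
            comps["harvest_src"] += _committed(stock, ev.year, ev.tau, years)
            comps["harvest_snk"] -= _committed(stock, ev.year, ev.tau_sink, years)
    del dens
    return ElucComponents(
        model_id="toy",
        years=years,
        components=comps,
        density_mode="transient" if density.mode == "transient" else "static",
    )


# ---------------------------------------------------------------------------
# PFT world


def make_pft_world(
    years: np.ndarray,
    s2_total: np.ndarray,
    bias_target: np.ndarray,
    n_cells: int = 4,
    nbp_gap: float = 1.5,
) -> tuple[PftFluxGrid, PftGrid, PftGrid]:
    """A toy multi-cell PFT world whose cover-change bias is ``bias_target``.

    Three PFTs (forest, grass, crop).  Fixed (pre-industrial) cover is 50%
    forest / 40% grass per cell; under transient cover, forest is converted
    to grass so that the global reconstruction bias equals the target in
    closed form: forest NBP density exceeds grass density by ``nbp_gap``,
    and the converted fraction in year t is
    bias_target(t) / (nbp_gap × total area).  Densities are set so the
    fixed-cover global sum reproduces ``s2_total`` exactly.  Crop never
    carries a density (NaN) and never carries cover, exercising the
    missing-PFT path only when a caller puts cover on it.
    """
    years = np.asarray(years, int)
    s2_total = np.asarray(s2_total, float)
    bias_target = np.asarray(bias_target, float)
    pfts = ["forest", "grass", "crop"]
    cell_ids = [f"cell{i}" for i in range(n_cells)]
    areas = np.ones(n_cells)
    total_area = areas.sum()

    # per-year densities from the level and gap constraints:
    # total_area (0.5 d_f + 0.4 d_g) = s2_total and d_f − d_g = nbp_gap
    d_g = (s2_total / total_area - 0.5 * nbp_gap) / 0.9
    d_f = d_g + nbp_gap

    nbp = np.full((n_cells, 3, years.size), np.nan)
    nbp[:, 0, :] = d_f
    nbp[:, 1, :] = d_g

    cover_s2 = np.zeros((n_cells, 3, years.size))
    cover_s2[:, 0, :] = 0.5
    cover_s2[:, 1, :] = 0.4

    conv = bias_target / (nbp_gap * total_area)     # converted forest fraction
    if np.any(conv > 0.5):
        raise ValueError("bias target exceeds what forest conversion can supply")
    if np.any(conv < 0):
        raise ValueError("bias target must be non-negative")
    cover_s3 = cover_s2.copy()
    cover_s3[:, 0, :] -= conv
    cover_s3[:, 1, :] += conv

    flux = PftFluxGrid(cell_ids, pfts, years, nbp)
    s2 = PftGrid(cell_ids, areas, pfts, years, cover_s2)
    s3 = PftGrid(cell_ids, areas, pfts, years, cover_s3)
    return flux, s2, s3


# ---------------------------------------------------------------------------
# full world


def _truth_trajectories(cfg: WorldConfig, rngs: list[np.random.Generator]):
    x = cfg.x
    years = cfg.years
    n = years.size
    phi = cfg.ar1_phi
    efos = 2.5 + 5.5 * x + 2.4 * x**2 + _ar1(rngs[0], n, phi, cfg.sigma_efos)
    eluc_static = 1.45 - 0.35 * x + _ar1(rngs[1], n, phi, cfg.sigma_eluc)
    co2 = co2_trajectory(years)
    density_factor = 1.0 + cfg.density_beta * np.log(co2 / CO2_PREINDUSTRIAL)
    eluc_true = eluc_static * density_factor
    sland = 0.35 + 2.53 * x + _ar1(rngs[2], n, phi, cfg.sigma_sland)
    socean = 1.0 + 2.26 * x + _ar1(rngs[3], n, phi, cfg.sigma_socean)
    return efos, eluc_static, eluc_true, sland, socean, co2, density_factor


_STATIC_COMPONENT_SHAPES = {
    # base level and linear-in-x slope of each static E_LUC subcomponent;
    # they sum to the 1.45 − 0.35 x static net trajectory
    "deforestation": (1.75, -0.15),
    "regrowth": (-0.60, 0.0),
    "harvest_src": (0.55, -0.10),
    "harvest_snk": (-0.30, 0.0),
    "other": (0.05, -0.10),
}


def simulate_world(config: WorldConfig | None = None) -> SyntheticWorld:
    """Generate the full synthetic input bundle for one seed."""
    cfg = config or WorldConfig()
    years = cfg.years
    n = years.size
    x = cfg.x
    phi = cfg.ar1_phi
    (r_truth, r_book, r_dgvm, r_gobm, r_fco2, r_inv, r_clim) = (
        _streams(cfg.seed, 7)
    )
    truth_rngs = _streams(int(r_truth.integers(2**31)), 4)
    efos, eluc_static_truth, eluc_true, sland, socean, co2, density_factor = (
        _truth_trajectories(cfg, truth_rngs)
    )

    # ---- bookkeeping ensemble (transient-density correction) -------------
    book_rngs = _streams(int(r_book.integers(2**31)), cfg.n_bookkeeping)
    static_models: list[ElucComponents] = []
    transient_models: list[ElucComponents] = []
    transient_nets = []
    for i, rng in enumerate(book_rngs):
        level = 1.0 + rng.normal(0.0, cfg.bookkeeping_level_sd)
        noise = 1.0 + _ar1(rng, n, phi, cfg.spread_bookkeeping)
        comps_static = {
            name: (a + b * x) * level * noise
            for name, (a, b) in _STATIC_COMPONENT_SHAPES.items()
        }
        static = ElucComponents(f"book{i}", years, comps_static, "static")
        comps_tr = {k: v * density_factor for k, v in comps_static.items()}
        transient = ElucComponents(
            f"book{i}", years, comps_tr, "transient"
        )
        static_models.append(static)
        transient_nets.append(transient.net.values)
        if i < 2:
            transient_models.append(transient)
    eluc_obs_values = np.mean([m.net.values for m in static_models], axis=0)
    eluc_truth_values = np.mean(transient_nets, axis=0)
    delta_l_true = eluc_truth_values - eluc_obs_values

    # ---- land sink: RSS + LCE biased DGVM S2 ensemble ---------------------
    lce_ramp = linear_ramp(years, start=cfg.first_year, end=cfg.last_year - 9)
    lce_corr = cfg.lateral.organic_share - cfg.lateral.f_is - cfg.lateral.f_ie
    lce_true = lce_corr * lce_ramp
    dgvm_rngs = _streams(int(r_dgvm.integers(2**31)), cfg.n_dgvm)
    rss_true = cfg.rss_slope * x
    dgvm_s2: dict[str, FluxSeries] = {}
    pft_worlds = {}
    rss_member_true = {}
    for i, rng in enumerate(dgvm_rngs):
        slope_m = cfg.rss_slope + rng.normal(0.0, cfg.rss_member_sd)
        bias_m = np.clip(slope_m, 0.0, None) * x
        s2_m = sland + bias_m + lce_true + _ar1(rng, n, phi, cfg.spread_dgvm)
        name = f"dgvm{i}"
        dgvm_s2[name] = FluxSeries("S_LAND", years, s2_m)
        pft_worlds[name] = make_pft_world(years, s2_m, bias_m)
        rss_member_true[name] = bias_m

    # ---- ocean ensembles --------------------------------------------------
    gobm_rngs = _streams(int(r_gobm.integers(2**31)), cfg.n_gobm)
    fco2_rngs = _streams(int(r_fco2.integers(2**31)), cfg.n_fco2)
    gobm = EnsembleSeries(
        {
            f"gobm{i}": FluxSeries(
                "S_OCEAN",
                years,
                socean / (1.0 + cfg.gobm_bias_fraction)
                + _ar1(rng, n, phi, cfg.spread_gobm),
            )
            for i, rng in enumerate(gobm_rngs)
        }
    )
    fco2 = EnsembleSeries(
        {
            f"fco2_{i}": FluxSeries(
                "S_OCEAN",
                years,
                socean - cfg.skin_deficit + _ar1(rng, n, phi, cfg.spread_fco2),
            )
            for i, rng in enumerate(fco2_rngs)
        }
    )

    # ---- truth budget (closed by construction) ----------------------------
    truth = BudgetTable.from_values(years, efos, eluc_true, sland, socean)
    gatm = truth.g_atm.values

    # ---- inversion members and conversion factors -------------------------
    inv_master = np.random.default_rng(int(r_inv.integers(2**31)))
    cf_true = cfg.cf_reference * (
        1.0 + _ar1(inv_master, n, phi, cfg.cf_interannual_sd)
    )
    inv_rngs = _streams(int(inv_master.integers(2**31)), cfg.n_inversions)
    inversions = []
    month_t = np.arange(cfg.first_year - 0.5, cfg.last_year + 1.5 + 1e-9, 1 / 12)
    for i, rng in enumerate(inv_rngs):
        net_input = gatm + _ar1(rng, n, phi, cfg.spread_inversion)
        cf_member = cf_true * (1.0 + rng.normal(0.0, cfg.cf_member_sd, n))
        growth = net_input / cf_member
        # integrate growth into 1-Jan boundary values, interpolate monthly,
        # then superpose a two-harmonic seasonal cycle
        boundaries = np.concatenate([[380.0], 380.0 + np.cumsum(growth)])
        boundary_t = np.arange(cfg.first_year, cfg.last_year + 2, dtype=float)
        base = np.interp(month_t, boundary_t, boundaries)
        seasonal = cfg.seasonal_amp_ppm * (
            np.cos(2 * np.pi * month_t) + 0.3 * np.sin(4 * np.pi * month_t)
        )
        inversions.append(
            InversionMember(
                member_id=f"inv{i}",
                years=years,
                net_input=net_input,
                mf_time=month_t,
                mf_ppm=base + seasonal,
            )
        )

    # ---- paired climate runs ---------------------------------------------
    clim_master = np.random.default_rng(int(r_clim.integers(2**31)))
    clim_land_true = cfg.clim_land_amp * x**cfg.clim_land_power
    clim_ocean_true = cfg.clim_ocean_amp * x**cfg.clim_ocean_power
    land_pairs, ocean_pairs = {}, {}
    land_rngs = _streams(int(clim_master.integers(2**31)), cfg.n_dgvm)
    ocean_rngs = _streams(int(clim_master.integers(2**31)), cfg.n_gobm)
    for i, rng in enumerate(land_rngs):
        scale = max(0.0, 1.0 + rng.normal(0.0, cfg.clim_member_sd))
        full = sland + _ar1(rng, n, phi, cfg.spread_dgvm)
        fixed = full + clim_land_true * scale
        land_pairs[f"dgvm{i}"] = (
            FluxSeries("S_LAND", years, full),
            FluxSeries("S_LAND", years, fixed),
        )
    for i, rng in enumerate(ocean_rngs):
        scale = max(0.0, 1.0 + rng.normal(0.0, cfg.clim_member_sd))
        full = socean + _ar1(rng, n, phi, cfg.spread_gobm)
        fixed = full + clim_ocean_true * scale
        ocean_pairs[f"gobm{i}"] = (
            FluxSeries("S_OCEAN", years, full),
            FluxSeries("S_OCEAN", years, fixed),
        )

    # ---- GCB-style biased baseline table ----------------------------------
    sland_obs = np.mean([s.values for s in dgvm_s2.values()], axis=0)
    socean_obs = 0.5 * (
        gobm.mean_series().values + fco2.mean_series().values
    )
    baseline = BudgetTable.from_values(
        years,
        efos,
        eluc_obs_values,
        sland_obs,
        socean_obs,
        g_atm=gatm,
        sigmas={
            "E_FOS": np.full(n, 0.5),
            "E_LUC": np.full(n, 0.7),
            "S_LAND": np.full(n, 0.9),
            "S_OCEAN": np.full(n, 0.4),
            "G_ATM": np.full(n, 0.07),
        },
    )

    return SyntheticWorld(
        config=cfg,
        truth=truth,
        co2_ppm=co2,
        baseline=baseline,
        bookkeeping_static=static_models,
        bookkeeping_transient=transient_models,
        delta_l_true=delta_l_true,
        delta_l_sigma=cfg.delta_l_model_sigma,
        dgvm_s2=dgvm_s2,
        pft_worlds=pft_worlds,
        rss_true=rss_true,
        rss_member_true=rss_member_true,
        lce_true=lce_true,
        lce_ramp=lce_ramp,
        gobm=gobm,
        fco2=fco2,
        inversions=inversions,
        cf_true=cf_true,
        land_pairs=land_pairs,
        ocean_pairs=ocean_pairs,
        clim_land_true=clim_land_true,
        clim_ocean_true=clim_ocean_true,
    )
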