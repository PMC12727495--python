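"""Plain-text interchange formats for the pipeline stages.

All tabular data travel as UTF-8 CSV with '.' decimal separators:

* flux series — one row per (component, member, year): columns
  ``component, member, year, value_gtc_per_yr, sigma_gtc_per_yr``; member is
  empty for consensus series;
* bookkeeping tables — one row per (model, density_mode, component, year);
* PFT grids — long format ``model, cell, pft, year, cover_fraction, area``
  for cover and ``model, cell, pft, year, nbp_density`` for fluxes;
* inversion members — a net-input table and a mole-fraction record;
* scalar correction parameters — a single YAML document.

Floats are written with 17 significant digits so a fixed seed reproduces
byte-identical files across platforms.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .convfactor import InversionMember
from .core import BudgetTable, FluxSeries
from .eluc import ELUC_SUBCOMPONENTS, ElucComponents
from .lateral import LateralFluxPerturbation
from .ocean import OceanCorrectionSpec
from .rss import PftFluxGrid, PftGrid

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "read_budget_csv",
    "write_eluc_csv",
    "read_eluc_csv",
    "write_pft_csv",
    "read_pft_csv",
    "write_inversions_csv",
    "read_inversions_csv",
    "write_config_yaml",
    "read_config_yaml",
]

_FLOAT_FMT = "%.17g"


def _write(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# flux series


def write_series_csv(series: dict[str, FluxSeries] | list[FluxSeries], path) -> None:
    """Write flux series in the common long schema.

    ``series`` maps member id → series (member left empty for a plain
    list of consensus series).
    """
    if isinstance(series, list):
        frames = [s.to_frame() for s in series]
    else:
        frames = [s.to_frame(member) for member, s in series.items()]
    _write(pd.concat(frames, ignore_index=True), path)


def read_series_csv(path) -> dict[tuple[str, str], FluxSeries]:
    """Read the common schema; keys are (component, member)."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    out = {}
    for (component, member), grp in df.groupby(["component", "member"], dropna=False):
        grp = grp.sort_values("year")
        member = "" if pd.isna(member) else str(member)
        sigma = grp["sigma_gtc_per_yr"].to_numpy(float)
        out[(component, member)] = FluxSeries(
            str(component),
            grp["year"].to_numpy(int),
            grp["value_gtc_per_yr"].to_numpy(float),
            None if np.all(np.isnan(sigma)) else sigma,
        )
    return out


def read_budget_csv(path) -> BudgetTable:
    """Read a five-component consensus budget table."""
    series = read_series_csv(path)
    by_comp = {comp: s for (comp, member), s in series.items() if member == ""}
    try:
        return BudgetTable(
            by_comp["E_FOS"], by_comp["E_LUC"], by_comp["S_LAND"],
            by_comp["S_OCEAN"], by_comp["G_ATM"],
        )
    except KeyError as exc:
        raise ValueError(f"budget component missing from {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# bookkeeping tables


def write_eluc_csv(models: list[ElucComponents], path) -> None:
    rows = []
    for m in models:
        for name in ELUC_SUBCOMPONENTS:
            rows.append(
                pd.DataFrame(
                    {
                        "model": m.model_id,
                        "density_mode": m.density_mode,
                        "component": name,
                        "year": m.years,
                        "value_gtc_per_yr": m.components[name],
                    }
                )
            )
    _write(pd.concat(rows, ignore_index=True), path)


def read_eluc_csv(path) -> list[ElucComponents]:
    df = pd.read_csv(path)
    out = []
    for (model, mode), grp in df.groupby(["model", "density_mode"]):
        years = np.sort(grp["year"].unique())
        comps = {}
        for name, sub in grp.groupby("component"):
            sub = sub.sort_values("year")
            comps[name] = sub["value_gtc_per_yr"].to_numpy(float)
        out.append(ElucComponents(str(model), years, comps, str(mode)))
    return out


# ---------------------------------------------------------------------------
# PFT grids


def write_pft_csv(
    worlds: dict[str, tuple[PftFluxGrid, PftGrid, PftGrid]], directory
) -> None:
    """Write per-model (nbp, cover_s2, cover_s3) grids into a directory."""
    directory = Path(directory)
    cover_rows, nbp_rows = [], []
    for model, (nbp, s2, s3) in worlds.items():
        for label, grid in (("s2", s2), ("s3", s3)):
            for ci, cell in enumerate(grid.cell_ids):
                for pi, pft in enumerate(grid.pfts):
                    cover_rows.append(
                        pd.DataFrame(
                            {
                                "model": model,
                                "scenario": label,
                                "cell": cell,
                                "pft": pft,
                                "year": grid.years,
                                "cover_fraction": grid.cover[ci, pi],
                                "area": grid.areas[ci],
                            }
                        )
                    )
        for ci, cell in enumerate(nbp.cell_ids):
            for pi, pft in enumerate(nbp.pfts):
                nbp_rows.append(
                    pd.DataFrame(
                        {
                            "model": model,
                            "cell": cell,
                            "pft": pft,
                            "year": nbp.years,
                            "nbp_density": nbp.nbp[ci, pi],
                        }
                    )
                )
    _write(pd.concat(cover_rows, ignore_index=True), directory / "pft_cover.csv")
    _write(pd.concat(nbp_rows, ignore_index=True), directory / "pft_nbp.csv")


def _grid_from_frames(cover: pd.DataFrame, nbp: pd.DataFrame):
    # preserve first-appearance order so array axes survive the round trip
    cells = list(pd.unique(cover["cell"]))
    pfts = list(pd.unique(cover["pft"]))
    years = np.sort(cover["year"].unique())
    areas = np.array(
        [cover.loc[cover["cell"] == c, "area"].iloc[0] for c in cells]
    )

    def pivot(df, value):
        arr = np.full((len(cells), len(pfts), years.size), np.nan)
        ci = {c: i for i, c in enumerate(cells)}
        pi = {p: i for i, p in enumerate(pfts)}
        yi = {y: i for i, y in enumerate(years)}
        for row in df.itertuples(index=False):
            arr[ci[row.cell], pi[row.pft], yi[row.year]] = getattr(row, value)
        return arr

    s2 = pivot(cover[cover["scenario"] == "s2"], "cover_fraction")
    s3 = pivot(cover[cover["scenario"] == "s3"], "cover_fraction")
    dens = pivot(nbp, "nbp_density")
    return (
        PftFluxGrid(cells, pfts, years, dens),
        PftGrid(cells, areas, pfts, years, s2),
        PftGrid(cells, areas, pfts, years, s3),
    )


def read_pft_csv(directory) -> dict[str, tuple[PftFluxGrid, PftGrid, PftGrid]]:
    directory = Path(directory)
    cover = pd.read_csv(directory / "pft_cover.csv")
    nbp = pd.read_csv(directory / "pft_nbp.csv")
    out = {}
    for model in sorted(cover["model"].unique()):
        out[model] = _grid_from_frames(
            cover[cover["model"] == model], nbp[nbp["model"] == model]
        )
    return out


# ---------------------------------------------------------------------------
# inversions


def write_inversions_csv(members: list[InversionMember], directory) -> None:
    directory = Path(directory)
    net = pd.concat(
        [
            pd.DataFrame(
                {"member": m.member_id, "year": m.years, "net_input_gtc": m.net_input}
            )
            for m in members
        ],
        ignore_index=True,
    )
    _write(net, directory / "inversion_net_input.csv")
    mf = pd.concat(
        [
            pd.DataFrame(
                {"member": m.member_id, "decimal_year": m.mf_time, "ppm": m.mf_ppm}
            )
            for m in members
            if m.mf_time is not None
        ],
        ignore_index=True,
    )
    _write(mf, directory / "inversion_molefractions.csv")


def read_inversions_csv(directory) -> list[InversionMember]:
    directory = Path(directory)
    net = pd.read_csv(directory / "inversion_net_input.csv")
    mf_path = directory / "inversion_molefractions.csv"
    mf = pd.read_csv(mf_path) if mf_path.exists() else None
    members = []
    for member, grp in net.groupby("member"):
        grp = grp.sort_values("year")
        kwargs = {}
        if mf is not None and member in set(mf["member"]):
            rec = mf[mf["member"] == member].sort_values("decimal_year")
            kwargs = {
                "mf_time": rec["decimal_year"].to_numpy(float),
                "mf_ppm": rec["ppm"].to_numpy(float),
            }
        members.append(
            InversionMember(
                member_id=str(member),
                years=grp["year"].to_numpy(int),
                net_input=grp["net_input_gtc"].to_numpy(float),
                **kwargs,
            )
        )
    return members


# ---------------------------------------------------------------------------
# scalar configuration


def write_config_yaml(
    path,
    lateral: LateralFluxPerturbation,
    ocean: OceanCorrectionSpec,
    extra: dict | None = None,
) -> None:
    doc = {
        "lateral": {
            "f_li": lateral.f_li, "f_ia": lateral.f_ia, "f_is": lateral.f_is,
            "f_ie": lateral.f_ie,
            "dissolved_share": lateral.dissolved_share,
            "organic_share": lateral.organic_share,
            "f_li_sigma": lateral.f_li_sigma, "f_ia_sigma": lateral.f_ia_sigma,
            "f_is_sigma": lateral.f_is_sigma, "f_ie_sigma": lateral.f_ie_sigma,
            "correction_sigma": lateral.correction_sigma,
        },
        "ocean": {
            "gobm_scale_fraction": ocean.gobm_scale_fraction,
            "gobm_sigma_fraction": ocean.gobm_sigma_fraction,
            "cool_skin": ocean.cool_skin,
            "warm_layer": ocean.warm_layer,
            "fco2_sigma": ocean.fco2_sigma,
            "p_positive_gobm": ocean.p_positive_gobm,
            "p_positive_fco2": ocean.p_positive_fco2,
        },
    }
    if extra:
        doc.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_config_yaml(path) -> dict:
    """Parsed config with ``lateral`` and ``ocean`` realized as dataclasses."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    out = dict(doc)
    if "lateral" in doc:
        out["lateral"] = LateralFluxPerturbation(**doc["lateral"])
    if "ocean" in doc:
        out["ocean"] = OceanCorrectionSpec(**doc["ocean"])
    return out
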