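"""Simulation engine: the annual elevation loop, spin-up, scenario
forcing, Monte Carlo uncertainty, and DEM projection.

The model advances one year at a time. Each year: mineral deposition is
read from the precomputed elevation/deposition table at the current
elevation and ambient sediment concentration; plant cover steps by the
species-transition model; gross organic production (after the salinity
penalty) is split into labile and refractory pools, with the belowground
share distributed down the root profile; the labile pool decomposes by
age class and burial depth; and the surface elevation moves by the
budget ΔE = MAR + OAR − DECOMP − SLR, with all volume terms measured as
thickness changes of the cohort stack so closure is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .soil import (
    DecompParams,
    MixingModel,
    RootParams,
    SoilColumn,
    annual_elevation_step,
    apply_annual_decomposition,
    bulk_density,
    distribute_root_growth,
    erode_mass,
    split_organic_input,
    turnover_live_roots,
)
from .tides import (
    HarmonicSet,
    MarTable,
    SedimentParams,
    TideSeries,
    default_harmonics,
    mar_elevation_table,
    synthesize_tide,
)
from .vegetation import (
    CommunityState,
    SalinityScenario,
    SpeciesResponse,
    carbon_accumulation,
    classify_state,
    organic_production,
    step_cover,
)

__all__ = [
    "SiteParams",
    "SLRScenario",
    "SLR_TOTALS_CM",
    "SedimentScenario",
    "SeaLevelExtras",
    "Trajectory",
    "MarshModel",
    "build_slr_curve",
    "sediment_concentration",
    "spin_up",
    "equilibrium_elevation",
    "run_scenario",
    "monte_carlo",
    "threshold_sweep",
    "project_dem",
    "default_z0_grid_m",
]

#: total sea-level rise (cm) 2016-2100 for the four named scenarios
SLR_TOTALS_CM = {"low": 29.0, "int_low": 39.0, "mid": 99.0, "high": 167.0}
#: historic long-term SLR rate (cm/yr) used as the initial rate of the
#: nonlinear curves
_HISTORIC_RATE_CM_YR = 0.21
_PROJECTION_YEARS = 85  # 2016-2100


@dataclass(frozen=True)
class SiteParams:
    """Site configuration bundle: datums, tide range, calibrated sediment
    concentration, decomposition and mixing constants."""

    name: str = "synthetic"
    msl_navd_m: float = 1.02
    tide_range_m: float = 1.92
    ssc_mg_l: float = 69.0
    ssc_sd: float = 60.8
    decomp: DecompParams = field(default_factory=DecompParams)
    root: RootParams = field(default_factory=RootParams)
    mixing: MixingModel = field(default_factory=MixingModel)
    root_shoot: float = 0.05
    organic_scaler: float = 1.0
    organic_scaler_sd: float = 0.0
    tide_amp_rate: float = 0.043  # cm tide-range change per cm SLR


@dataclass(frozen=True)
class SLRScenario:
    """Named sea-level-rise scenario; ``curve_cm`` (cumulative offsets,
    year 0..n) may override the built-in shapes."""

    name: str = "low"
    curve_cm: np.ndarray | None = None

    def build(self, n_years: int = _PROJECTION_YEARS) -> np.ndarray:
        if self.curve_cm is not None:
            c = np.asarray(self.curve_cm, dtype=float)
            if c.size != n_years + 1:
                raise ValueError("override curve must have n_years+1 points")
            return c
        return build_slr_curve(self.name, n_years)


def build_slr_curve(name: str, n_years: int = _PROJECTION_YEARS) -> np.ndarray:
    """Cumulative sea-level offsets (cm) for years 0..n_years.

    The low and intermediate-low scenarios rise linearly to their totals
    (29 and 39 cm by 2100, i.e. 3.4 and 4.6 mm/yr); the mid and high
    scenarios follow a quadratic that starts at the historic rate and is
    constrained to the printed 2016-2100 total, so annual increments
    increase monotonically.
    """
    if name not in SLR_TOTALS_CM:
        raise KeyError(f"unknown SLR scenario {name!r}")
    total = SLR_TOTALS_CM[name]
    t = np.arange(n_years + 1, dtype=float)
    if name in ("low", "int_low"):
        return total * t / n_years
    a = _HISTORIC_RATE_CM_YR
    b = (total - a * n_years) / n_years**2
    return a * t + b * t**2


@dataclass(frozen=True)
class SedimentScenario:
    """Future sediment-supply rule applied to the calibrated historic
    concentration C0: historic (C0), constant (0.6·C0), declining
    (0.6·C0 shrinking 1.6 %/yr), increasing (1.25·C0)."""

    kind: str = "historic"

    def concentration(self, C0: float, t_years: float) -> float:
        return sediment_concentration(self.kind, C0, t_years)


def sediment_concentration(kind: str, C0: float, t_years: float) -> float:
    if kind == "historic":
        return C0
    if kind == "constant":
        return 0.6 * C0
    if kind == "declining":
        return 0.6 * C0 * (1.0 - 0.016) ** t_years
    if kind == "increasing":
        return 1.25 * C0
    raise KeyError(f"unknown sediment scenario {kind!r}")


@dataclass(frozen=True)
class SeaLevelExtras:
    """Short-period sea-level modulation: the 18.6-yr lunar nodal cycle
    (±2 cm), random ENSO years (±5 cm, mean return 4 yr), and tide-range
    amplification with cumulative SLR."""

    nodal_amplitude_cm: float = 2.0
    nodal_period_yr: float = 18.6
    enso_amplitude_cm: float = 5.0
    enso_return_yr: float = 4.0
    seed: int = 0
    enabled: bool = True

    def sea_level_offsets(self, n_years: int) -> np.ndarray:
        """Oscillatory MSL offsets (cm) for years 0..n_years (additive to
        the SLR curve); deterministic for a fixed seed."""
        t = np.arange(n_years + 1, dtype=float)
        if not self.enabled:
            return np.zeros(n_years + 1)
        nodal = self.nodal_amplitude_cm * np.sin(2.0 * np.pi * t / self.nodal_period_yr)
        rng = np.random.default_rng(self.seed)
        events = rng.random(n_years + 1) < 1.0 / self.enso_return_yr
        signs = rng.choice([-1.0, 1.0], size=n_years + 1)
        enso = np.where(events, signs * self.enso_amplitude_cm, 0.0)
        enso[0] = 0.0
        return nodal + enso


@dataclass
class Trajectory:
    """Per-year outputs of one simulation (arrays of length n_years+1 for
    elevation; n_years for fluxes)."""

    years: np.ndarray
    elevation_cm: np.ndarray  # rel. contemporary MSL, length n+1
    sea_level_cm: np.ndarray  # cumulative offset, length n+1
    car_g_m2_yr: np.ndarray
    mar_cm: np.ndarray
    oar_cm: np.ndarray
    decomp_cm: np.ndarray
    slr_cm: np.ndarray
    cover: np.ndarray  # (n, n_species)
    species_names: list[str]

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def total_cover(self) -> np.ndarray:
        return self.cover.sum(axis=1)

    @property
    def final_state(self) -> str:
        return classify_state(CommunityState(self.cover[-1]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "year": self.years,
                "elevation_cm": self.elevation_cm[1:],
                "sea_level_cm": self.sea_level_cm[1:],
                "car_g_m2_yr": self.car_g_m2_yr,
                "mar_cm": self.mar_cm,
                "oar_cm": self.oar_cm,
                "decomp_cm": self.decomp_cm,
                "slr_cm": self.slr_cm,
                "total_cover": self.total_cover,
            }
        )
        for j, name in enumerate(self.species_names):
            df[f"cover_{name}"] = self.cover[:, j]
        df["state"] = np.where(
            df["total_cover"] < 0.20, "mudflat", "vegetated"
        )
        return df


class MarshModel:
    """Site-configured marsh simulator.

    Owns the synthetic tide, the elevation/deposition tables (one per
    tide-range scale), and the species set; exposes the annual step used
    by every driver (spin-up, scenarios, calibration, fixtures).
    """

    def __init__(
        self,
        site: SiteParams,
        species: list[SpeciesResponse],
        sediment: SedimentParams | None = None,
        harmonics: HarmonicSet | None = None,
        tide: TideSeries | None = None,
        z_grid_m: np.ndarray | None = None,
    ) -> None:
        self.site = site
        self.species = species
        self.sediment = sediment if sediment is not None else SedimentParams(C0=site.ssc_mg_l)
        self.tide = (
            tide
            if tide is not None
            else synthesize_tide(harmonics or default_harmonics(), site.tide_range_m)
        )
        self.z_grid_m = (
            np.asarray(z_grid_m, float)
            if z_grid_m is not None
            else np.arange(-2.0, 5.501, 0.05)
        )
        self._tables: dict[float, MarTable] = {}
        self._table(1.0)

    # -- deposition tables ------------------------------------------------
    def _table(self, scale: float) -> MarTable:
        key = round(float(scale), 6)
        if key not in self._tables:
            tide = self.tide if key == 1.0 else self.tide.scaled(key)
            self._tables[key] = mar_elevation_table(tide, self.sediment, self.z_grid_m)
        return self._tables[key]

    def ensure_scales(self, max_scale: float, n: int = 4) -> None:
        """Precompute deposition tables spanning [1, max_scale]."""
        for s in np.linspace(1.0, max(max_scale, 1.0 + 1e-9), n):
            self._table(s)

    def components(self, z_m: float, scale: float = 1.0) -> tuple[float, float, float]:
        """(settle_unit, erode, inundation) at elevation z, interpolating
        between the cached tide-range scales."""
        keys = np.array(sorted(self._tables))
        if scale <= keys[0]:
            t = self._tables[keys[0]]
            return (
                float(np.interp(z_m, t.z_m, t.settle_unit)),
                float(np.interp(z_m, t.z_m, t.erode)),
                float(np.interp(z_m, t.z_m, t.inund)),
            )
        if scale >= keys[-1]:
            t = self._tables[keys[-1]]
            return (
                float(np.interp(z_m, t.z_m, t.settle_unit)),
                float(np.interp(z_m, t.z_m, t.erode)),
                float(np.interp(z_m, t.z_m, t.inund)),
            )
        hi = int(np.searchsorted(keys, scale))
        lo = hi - 1
        w = (scale - keys[lo]) / (keys[hi] - keys[lo])
        tl, th = self._tables[keys[lo]], self._tables[keys[hi]]
        out = []
        for attr in ("settle_unit", "erode", "inund"):
            vl = float(np.interp(z_m, tl.z_m, getattr(tl, attr)))
            vh = float(np.interp(z_m, th.z_m, getattr(th, attr)))
            out.append((1.0 - w) * vl + w * vh)
        return tuple(out)  # type: ignore[return-value]

    # -- initial conditions -----------------------------------------------
    def initial_column(self, z0_cm: float, base_thickness_cm: float = 100.0) -> SoilColumn:
        """Seed column: one thick pre-existing cohort of mineral-dominated
        soil (organic fraction 0.15, all refractory) under the surface at
        ``z0_cm``; the spin-up grows the realistic profile on top."""
        col = SoilColumn(
            mix=self.site.mixing,
            surface_elevation=z0_cm,
            live_root_density=self.site.root.live_density,
        )
        o = 0.15
        mass = base_thickness_cm * bulk_density(o, self.site.mixing)
        col.add_surface_cohort(0, mineral=(1 - o) * mass, refractory=o * mass)
        return col

    def initial_cover(self, z0_cm: float) -> CommunityState:
        return CommunityState(np.zeros(len(self.species)))

    # -- the annual step --------------------------------------------------
    def step_year(
        self,
        col: SoilColumn,
        state: CommunityState,
        year: int,
        C_mg_l: float,
        slr_cm: float,
        tide_scale: float = 1.0,
        salinity_factor: float = 1.0,
        scaler: float | None = None,
        decomp: DecompParams | None = None,
    ) -> tuple[CommunityState, dict]:
        """Advance the column and community one year; returns the new
        community state and the year's budget record."""
        site = self.site
        decomp = decomp if decomp is not None else site.decomp
        scaler = scaler if scaler is not None else site.organic_scaler
        z_cm = col.surface_elevation
        settle, erode, inund = self.components(z_cm / 100.0, tide_scale)
        mar_mass = C_mg_l * settle - erode  # g/cm²

        om0 = float((col.labile + col.refractory).sum())
        T0 = col.total_thickness
        if mar_mass < 0:
            erode_mass(col, -mar_mass)
        col.add_surface_cohort(year, mineral=max(mar_mass, 0.0))
        T1 = col.total_thickness
        mar_vol = T1 - T0

        state = step_cover(state, z_cm, self.species)
        gross_g_m2 = organic_production(z_cm, state, inund, self.species)
        gross_g_m2 *= scaler * salinity_factor
        gross = gross_g_m2 * 1e-4  # g/cm²
        turnover_live_roots(col, decomp)  # last year's roots die first
        below = site.root_shoot / (1.0 + site.root_shoot)
        lab, ref = split_organic_input(gross * (1.0 - below), decomp)
        col.labile[0] += lab
        col.refractory[0] += ref
        distribute_root_growth(col, gross * below, site.root, year)
        T2 = col.total_thickness
        oar_vol = T2 - T1

        apply_annual_decomposition(col, decomp, year)
        col.prune()
        T3 = col.total_thickness
        decomp_vol = T2 - T3

        annual_elevation_step(col, mar_vol, oar_vol, decomp_vol, slr_cm)
        # net retention of dead soil organic matter (live roots are
        # standing biomass, not yet soil carbon)
        net_om = float((col.labile + col.refractory).sum()) - om0
        record = {
            "mar_cm": mar_vol,
            "oar_cm": oar_vol,
            "decomp_cm": decomp_vol,
            "slr_cm": slr_cm,
            "car": carbon_accumulation(net_om * 1e4),
            "cover": state.cover.copy(),
        }
        return state, record

    def run_years(
        self,
        col: SoilColumn,
        state: CommunityState,
        C_by_year: np.ndarray,
        slr_by_year: np.ndarray,
        tide_scale_by_year: np.ndarray | None = None,
        salinity_factor_by_year: np.ndarray | None = None,
        start_year: int = 1,
        scaler: float | None = None,
        decomp: DecompParams | None = None,
        sea_level_cm: np.ndarray | None = None,
    ) -> Trajectory:
        """Run the annual loop for len(C_by_year) years, mutating ``col``."""
        n = len(C_by_year)
        ones = np.ones(n)
        scales = tide_scale_by_year if tide_scale_by_year is not None else ones
        sal = salinity_factor_by_year if salinity_factor_by_year is not None else ones
        elev = np.empty(n + 1)
        elev[0] = col.surface_elevation
        mar = np.empty(n)
        oar = np.empty(n)
        dec = np.empty(n)
        car = np.empty(n)
        cover = np.empty((n, len(self.species)))
        for k in range(n):
            state, rec = self.step_year(
                col,
                state,
                year=start_year + k,
                C_mg_l=float(C_by_year[k]),
                slr_cm=float(slr_by_year[k]),
                tide_scale=float(scales[k]),
                salinity_factor=float(sal[k]),
                scaler=scaler,
                decomp=decomp,
            )
            elev[k + 1] = col.surface_elevation
            mar[k], oar[k], dec[k] = rec["mar_cm"], rec["oar_cm"], rec["decomp_cm"]
            car[k] = rec["car"]
            cover[k] = rec["cover"]
        sl = (
            sea_level_cm
            if sea_level_cm is not None
            else np.concatenate(([0.0], np.cumsum(slr_by_year)))
        )
        return Trajectory(
            years=np.arange(start_year, start_year + n),
            elevation_cm=elev,
            sea_level_cm=sl,
            car_g_m2_yr=car,
            mar_cm=mar,
            oar_cm=oar,
            decomp_cm=dec,
            slr_cm=np.asarray(slr_by_year, float),
            cover=cover,
            species_names=[sp.name for sp in self.species],
        )


# -- spin-up ---------------------------------------------------------------

def spin_up(
    model: MarshModel,
    z0_cm: float,
    years: int = 200,
    rate_bounds_mm_yr: tuple[float, float] = (0.0, 20.0),
    tol_cm: float = 0.1,
    max_iter: int = 60,
) -> tuple[SoilColumn, CommunityState, float]:
    """Find the constant SLR rate that leaves the marsh at its starting
    elevation after a 200-year run, building the initial soil profile.

    Bisection on the rate; if even the bounds do not bracket (the marsh
    gains elevation at the upper bound, or loses at zero), the boundary
    rate is returned with a warning. Returns (column, community, rate in
    mm/yr) with the column equilibrated at the returned rate.
    """

    def run(rate_mm: float) -> tuple[SoilColumn, CommunityState, float]:
        col = model.initial_column(z0_cm)
        state = model.initial_cover(z0_cm)
        C = np.full(years, model.site.ssc_mg_l)
        slr = np.full(years, rate_mm / 10.0)
        traj = model.run_years(col, state, C, slr)
        final = CommunityState(traj.cover[-1])
        return col, final, col.surface_elevation - z0_cm

    lo, hi = rate_bounds_mm_yr
    col_lo, st_lo, f_lo = run(lo)
    if f_lo < -tol_cm:
        warnings.warn(
            "marsh loses elevation even with no sea-level rise; returning the lower bound"
        )
        return col_lo, st_lo, lo
    col_hi, st_hi, f_hi = run(hi)
    if f_hi > tol_cm:
        warnings.warn(
            "marsh keeps pace even at the upper rate bound; returning the upper bound"
        )
        return col_hi, st_hi, hi
    best = (col_lo, st_lo, lo, abs(f_lo))
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        col_m, st_m, f_m = run(mid)
        if abs(f_m) < best[3]:
            best = (col_m, st_m, mid, abs(f_m))
        if abs(f_m) < tol_cm:
            return col_m, st_m, mid
        if f_m > 0:
            lo = mid
        else:
            hi = mid
    return best[0], best[1], best[2]


def equilibrium_elevation(
    model: MarshModel,
    rate_cm_yr: float,
    bounds_cm: tuple[float, float] = (-40.0, 250.0),
    years: int = 120,
    settle_in: int = 60,
    iters: int = 18,
) -> float:
    """Elevation (cm, MSL) at which the marsh neither gains nor loses
    elevation under a constant SLR rate — the dynamic-equilibrium
    position a long-established marsh occupies.

    Bisection on the late-run elevation drift (the first ``settle_in``
    years absorb the cold-start transient).
    """

    def drift(z: float) -> float:
        col = model.initial_column(z)
        state = model.initial_cover(z)
        traj = model.run_years(
            col,
            state,
            np.full(years, model.site.ssc_mg_l),
            np.full(years, rate_cm_yr),
        )
        return col.surface_elevation - traj.elevation_cm[settle_in]

    # drift is non-monotone (negative on the erosional flat, positive in
    # the vegetated band, negative again above the accretion limit);
    # the stable equilibrium is the highest +/- crossing
    zs = np.linspace(bounds_cm[0], bounds_cm[1], 11)
    ds = [drift(z) for z in zs]
    bracket = None
    for i in range(len(zs) - 1, 0, -1):
        if ds[i - 1] > 0 and ds[i] <= 0:
            bracket = (zs[i - 1], zs[i])
            break
    if bracket is None:
        return float(zs[int(np.argmax(ds))])
    lo, hi = bracket
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if drift(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# -- scenario runs ----------------------------------------------------------

def run_scenario(
    model: MarshModel,
    start: float | tuple[SoilColumn, CommunityState],
    slr: str | SLRScenario = "low",
    sediment: str | SedimentScenario = "historic",
    salinity: SalinityScenario | None = None,
    extras: SeaLevelExtras | None = None,
    n_years: int = _PROJECTION_YEARS,
    seed: int = 0,
    C0: float | None = None,
    scaler: float | None = None,
    decomp: DecompParams | None = None,
    omega: float | None = None,
) -> Trajectory:
    """Run a forward scenario from 2016-equivalent conditions.

    ``start`` is either an initial elevation (cm, MSL; a spin-up is run
    first) or a (column, community) pair from a previous spin-up. The
    same seed always yields an identical trajectory.
    """
    site = model.site
    if isinstance(slr, str):
        slr = SLRScenario(slr)
    if isinstance(sediment, str):
        sediment = SedimentScenario(sediment)
    salinity = salinity if salinity is not None else SalinityScenario(0.0)
    extras = extras if extras is not None else SeaLevelExtras(seed=seed, enabled=False)

    if isinstance(start, (int, float)):
        col, state, _ = spin_up(model, float(start))
        col, state = col.copy(), state.copy()
    else:
        col, state = start[0].copy(), start[1].copy()

    curve = slr.build(n_years)
    osc = extras.sea_level_offsets(n_years)
    sea_level = curve + osc
    slr_inc = np.diff(sea_level)

    range_cm = site.tide_range_m * 100.0
    scales = 1.0 + site.tide_amp_rate * curve / range_cm
    if scales.max() > 1.0 + 1e-9:
        model.ensure_scales(float(scales.max()))

    C0 = C0 if C0 is not None else site.ssc_mg_l
    t = np.arange(n_years, dtype=float)
    C = np.array([sediment.concentration(C0, tk) for tk in t])
    om = omega if omega is not None else salinity.omega
    sal_factor = np.maximum(0.0, 1.0 - om * salinity.delta_psu(t))

    start_year = int(col.deposition_year[0]) + 1 if len(col) else 1
    return model.run_years(
        col,
        state,
        C_by_year=C,
        slr_by_year=slr_inc,
        tide_scale_by_year=scales[1:],
        salinity_factor_by_year=sal_factor,
        start_year=start_year,
        scaler=scaler,
        decomp=decomp,
        sea_level_cm=sea_level,
    )


# -- Monte Carlo -------------------------------------------------------------

def monte_carlo(
    model: MarshModel,
    start: float | tuple[SoilColumn, CommunityState],
    n: int = 100,
    seed: int = 0,
    slr: str | SLRScenario = "low",
    sediment: str | SedimentScenario = "historic",
    salinity: SalinityScenario | None = None,
    extras: SeaLevelExtras | None = None,
    n_years: int = _PROJECTION_YEARS,
) -> tuple[list[Trajectory], pd.DataFrame, pd.DataFrame]:
    """Propagate parameter uncertainty with n Monte Carlo draws.

    Each draw samples the sediment concentration, organic scaler,
    decomposition A values, and salinity penalty uniformly within ±1 SD
    of their means; the sea-level forcing realization is shared across
    draws so ensemble spread reflects parameter uncertainty alone.
    Returns (trajectories, per-year summary, sampled-parameter log).
    """
    site = model.site
    salinity = salinity if salinity is not None else SalinityScenario(0.0)
    rng = np.random.default_rng(seed)

    def draw(mu: float, sd: float, lo: float | None = None, hi: float | None = None) -> float:
        v = rng.uniform(mu - sd, mu + sd)
        if lo is not None:
            v = max(v, lo)
        if hi is not None:
            v = min(v, hi)
        return v

    if isinstance(start, (int, float)):
        start = spin_up(model, float(start))[:2]

    trajectories: list[Trajectory] = []
    rows = []
    for i in range(n):
        C0 = draw(site.ssc_mg_l, site.ssc_sd, lo=0.0)
        scaler = draw(site.organic_scaler, site.organic_scaler_sd, lo=0.0)
        A = tuple(
            draw(a, site.decomp.A_sd, lo=1e-6, hi=1.0 - 1e-6) for a in site.decomp.A
        )
        om = draw(salinity.omega, salinity.omega_sd, lo=0.0)
        dec = replace(site.decomp, A=A)
        traj = run_scenario(
            model,
            start,
            slr=slr,
            sediment=sediment,
            salinity=salinity,
            extras=extras,
            n_years=n_years,
            seed=seed,
            C0=C0,
            scaler=scaler,
            decomp=dec,
            omega=om,
        )
        trajectories.append(traj)
        rows.append(
            {"draw": i, "C0_mg_l": C0, "organic_scaler": scaler, "A1": A[0], "A2": A[1], "A3": A[2], "omega": om}
        )

    elev = np.stack([t.elevation_cm[1:] for t in trajectories])
    car = np.stack([t.car_g_m2_yr for t in trajectories])
    summary = pd.DataFrame(
        {
            "year": trajectories[0].years,
            "elev_mean_cm": elev.mean(axis=0),
            "elev_sd_cm": elev.std(axis=0),
            "car_mean": car.mean(axis=0),
            "car_sd": car.std(axis=0),
        }
    )
    return trajectories, summary, pd.DataFrame(rows)


# -- SLR threshold sweep ------------------------------------------------------

def threshold_sweep(
    model: MarshModel,
    z0_cm: float,
    rates_mm_yr: np.ndarray | None = None,
    years: int = 300,
    sediment: str = "historic",
) -> tuple[pd.DataFrame, float | None]:
    """Run constant linear SLR rates (default 1-10 mm/yr) for 300 years
    from a common spin-up and report whether the marsh persists and its
    end-of-run carbon accumulation rate.

    The threshold is the smallest rate whose end state is mudflat (total
    cover < 20%); None if the marsh persists at every rate tested.
    """
    rates = (
        np.asarray(rates_mm_yr, float)
        if rates_mm_yr is not None
        else np.arange(1.0, 10.1, 1.0)
    )
    col0, state0, _ = spin_up(model, z0_cm)
    rows = []
    threshold = None
    for r in rates:
        col, state = col0.copy(), state0.copy()
        C = np.array(
            [sediment_concentration(sediment, model.site.ssc_mg_l, t) for t in range(years)]
        )
        slr = np.full(years, r / 10.0)
        start_year = int(col.deposition_year[0]) + 1
        traj = model.run_years(col, state, C, slr, start_year=start_year)
        persisted = traj.final_state == "vegetated"
        end_car = float(np.mean(traj.car_g_m2_yr[-10:]))
        if not persisted and threshold is None:
            threshold = float(r)
        rows.append(
            {
                "rate_mm_yr": r,
                "persisted": persisted,
                "end_car_g_m2_yr": end_car,
                "end_elevation_cm": traj.elevation_cm[-1],
                "end_cover": traj.total_cover[-1],
            }
        )
    return pd.DataFrame(rows), threshold


# -- DEM projection -----------------------------------------------------------

def default_z0_grid_m() -> np.ndarray:
    """Initial-elevation grid: -0.5 to 2.0 m by 0.1 m, then 2.5 to 5.0 m
    by 0.5 m (covers potential upland transgression)."""
    return np.round(
        np.concatenate([np.arange(-0.5, 2.001, 0.1), np.arange(2.5, 5.001, 0.5)]), 3
    )


def project_dem(
    dem_m: np.ndarray,
    trajectories: dict[float, Trajectory],
    nodata_mask: np.ndarray | None = None,
    return_rasters: bool = False,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Interpolate per-initial-elevation trajectories across a DEM.

    Each valid pixel's annual elevation is the linear interpolation, in
    initial elevation, between the bracketing trajectories; pixels
    outside the trajectory grid are masked and counted. Returns a
    per-year summary (mean/SD elevation, mudflat fraction, masked pixel
    count) and optionally the (n_years, *dem.shape) elevation stack.
    """
    z0 = np.array(sorted(trajectories))
    if z0.size < 2:
        raise ValueError("need at least two initial-elevation trajectories")
    trajs = [trajectories[z] for z in z0]
    n_pts = trajs[0].elevation_cm.size
    if any(t.elevation_cm.size != n_pts for t in trajs):
        raise ValueError("trajectories must share a common horizon")
    E = np.stack([t.elevation_cm for t in trajs], axis=1)  # (n+1, K)
    cov0 = np.stack([t.total_cover for t in trajs], axis=1)  # (n, K)
    cov = np.vstack([cov0[:1], cov0])  # carry year-1 cover for year 0

    dem = np.asarray(dem_m, dtype=float)
    invalid = ~np.isfinite(dem)
    if nodata_mask is not None:
        invalid |= nodata_mask
    out_of_range = (~invalid) & ((dem < z0[0]) | (dem > z0[-1]))
    valid = ~(invalid | out_of_range)
    pix = dem[valid]

    rows = []
    stack = np.full((n_pts, *dem.shape), np.nan) if return_rasters else None
    for k in range(n_pts):
        ev = np.interp(pix, z0, E[k])
        cv = np.interp(pix, z0, cov[k])
        rows.append(
            {
                "year_index": k,
                "elev_mean_cm": float(ev.mean()),
                "elev_sd_cm": float(ev.std()),
                "mudflat_fraction": float(np.mean(cv < 0.20)),
                "n_valid": int(pix.size),
                "n_masked": int(out_of_range.sum() + invalid.sum()),
            }
        )
        if return_rasters:
            plane = np.full(dem.shape, np.nan)
            plane[valid] = ev
            stack[k] = plane
    return pd.DataFrame(rows), stack
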