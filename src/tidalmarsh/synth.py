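"""Synthetic fixtures: cores, tides, vegetation surveys, and DEMs.

Every generator is a pure function of its spec and seed, and each output
carries (or returns alongside) the true generating parameters so the
calibration machinery can be exercised as a round-trip identity test.
Synthetic cores are produced *by* the forward model itself — run for a
century and a half under the sea-level hindcast with known sediment
concentration and organic scaler — so parameter recovery is well posed.

Site parameter presets for three San Francisco Bay estuary marshes along
the salinity gradient (a salt marsh, a brackish marsh, and an oligohaline
island marsh) are included, together with plausible suitability and
productivity shapes for the five common species those communities use;
the published study reports the site constants but only plots the
productivity curves, so the curve shapes here are package fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .calibration import CoreProfile, MSLHindcast
from .engine import MarshModel, SiteParams
from .raster import AsciiGrid
from .soil import DecompParams
from .vegetation import SpeciesResponse

__all__ = [
    "SyntheticSiteSpec",
    "species_set",
    "site_params",
    "SITE_PRESETS",
    "make_model",
    "make_synthetic_core",
    "make_synthetic_survey",
    "make_synthetic_dem",
]


# -- species fixtures -----------------------------------------------------

def _triangle(lo: float, peak: float, hi: float, n: int = 21) -> tuple[np.ndarray, np.ndarray]:
    z = np.linspace(lo, hi, n)
    s = np.where(z <= peak, (z - lo) / max(peak - lo, 1e-9), (hi - z) / max(hi - peak, 1e-9))
    return z, np.clip(s, 0.0, 1.0)


def _species_defs(tide_range_cm: float) -> dict[str, dict]:
    """Per-species fixture parameters; suitability spans scale with the
    tide range R (z in cm MSL). Productivity polynomials are total dry
    biomass (g m⁻² yr⁻¹) against percent time inundated.

    Spans sit in the intertidal frame the way these species zone in the
    field: MHHW lies near +0.5R, so upper limits fall at or a little
    above MHHW and lower limits between MTL and MHW."""
    R = tide_range_cm
    return {
        # succulent high-marsh dominant: monotone decline with flooding
        "S.pacifica": dict(span=(0.30 * R, 0.50 * R, 0.62 * R), poly=(1200.0, -8.0, -0.15), r1=0.6),
        # low-marsh cordgrass: unimodal, peak ~40% inundation
        "S.foliosa": dict(span=(0.00 * R, 0.25 * R, 0.42 * R), poly=(0.0, 40.0, -0.5), r1=1.2),
        # brackish bulrush: unimodal, peak ~25%
        "B.maritimus": dict(span=(0.15 * R, 0.35 * R, 0.52 * R), poly=(337.5, 45.0, -0.9), r1=0.9),
        # mid-marsh sedge: unimodal, peak ~30%
        "S.americanus": dict(span=(0.10 * R, 0.32 * R, 0.55 * R), poly=(160.0, 36.0, -0.6), r1=1.0),
        # tule: unimodal, peak ~20%, tolerant of deep flooding
        "S.acutus": dict(span=(-0.05 * R, 0.20 * R, 0.45 * R), poly=(680.0, 32.0, -0.8), r1=0.8),
    }


#: site community composition (dominants from the field surveys)
_COMMUNITIES = {
    "petaluma": ["S.pacifica", "B.maritimus", "S.foliosa"],
    "rush_ranch": ["S.pacifica", "S.acutus", "S.americanus"],
    "browns_island": ["S.acutus", "S.americanus"],
}


def species_set(
    names: list[str] | str,
    tide_range_m: float,
    o_scale: float = 0.15,
) -> list[SpeciesResponse]:
    """Build the species fixtures for a named community (or explicit list
    of species names) at a given tide range.

    ``o_scale`` converts marsh-organ total dry biomass to gross soil
    organic input (litter plus root contribution actually reaching the
    soil); the default keeps net organic retention at full cover near the
    100-200 g m-2 yr-1 observed in dated cores, so the site-level
    calibration scaler is a neutral multiplier around 1."""
    if isinstance(names, str):
        names = _COMMUNITIES[names]
    defs = _species_defs(tide_range_m * 100.0)
    out = []
    for n in names:
        d = defs[n]
        z, s = _triangle(*d["span"])
        out.append(
            SpeciesResponse(
                name=n,
                suitability_z_cm=z,
                suitability_s=s,
                poly=d["poly"],
                r1=d["r1"],
                o_scale=o_scale,
            )
        )
    return out


# -- site presets ---------------------------------------------------------

SITE_PRESETS: dict[str, SiteParams] = {
    "petaluma": SiteParams(
        name="petaluma",
        msl_navd_m=1.02,
        tide_range_m=1.92,
        ssc_mg_l=69.0,
        ssc_sd=60.8,
        organic_scaler=1.0,
        organic_scaler_sd=0.25,
        decomp=DecompParams(A=(0.69, 0.91, 0.94), A_sd=0.05, refractory_r=0.662),
        tide_amp_rate=0.043,
    ),
    "rush_ranch": SiteParams(
        name="rush_ranch",
        msl_navd_m=1.12,
        tide_range_m=1.76,
        ssc_mg_l=75.3,
        ssc_sd=40.3,
        organic_scaler=1.0,
        organic_scaler_sd=0.25,
        decomp=DecompParams(A=(0.55, 0.83, 0.89), A_sd=0.05, refractory_r=0.505),
        tide_amp_rate=0.024,
    ),
    "browns_island": SiteParams(
        name="browns_island",
        msl_navd_m=1.095,
        tide_range_m=1.39,
        ssc_mg_l=19.0,
        ssc_sd=10.1,
        organic_scaler=1.0,
        organic_scaler_sd=0.25,
        decomp=DecompParams(A=(0.55, 0.83, 0.89), A_sd=0.05, refractory_r=0.394),
        tide_amp_rate=0.061,
    ),
}


def site_params(name: str, **overrides) -> SiteParams:
    return replace(SITE_PRESETS[name], **overrides)


@dataclass(frozen=True)
class SyntheticSiteSpec:
    """Ground truth for a synthetic site: the generating parameters the
    calibration should recover, plus noise levels and the seed."""

    site: str = "petaluma"
    C_true_mg_l: float = 50.0
    scaler_true: float = 1.0
    z0_cm: float | None = None
    noise_rho: float = 0.05
    noise_o: float = 0.05
    seed: int = 0

    def params(self) -> SiteParams:
        return site_params(
            self.site, organic_scaler=self.scaler_true, ssc_mg_l=self.C_true_mg_l
        )


def make_model(spec: SyntheticSiteSpec | str = "petaluma", **kwargs) -> MarshModel:
    """Convenience constructor: site preset + species fixtures + tide."""
    if isinstance(spec, str):
        site = site_params(spec)
        return MarshModel(site, species_set(spec, site.tide_range_m), **kwargs)
    site = spec.params()
    return MarshModel(site, species_set(spec.site, site.tide_range_m), **kwargs)


# -- synthetic cores ------------------------------------------------------

def make_synthetic_core(
    spec: SyntheticSiteSpec,
    years: int = 150,
    model: MarshModel | None = None,
) -> tuple[CoreProfile, dict]:
    """Generate a dated soil core by running the forward model under the
    sea-level hindcast with known (C_true, scaler_true).

    The marsh is first equilibrated by spin-up at the generating
    concentration (dated cores come from long-established marshes near
    dynamic equilibrium), then run forward under the sea-level hindcast.
    The final column is discretized into 2-cm intervals; multiplicative
    lognormal noise is applied to bulk density and organic fraction; the
    realized 50-yr accretion rate (depth to the surface of 50 years ago)
    is attached. Returns (core, manifest-of-truth).
    """
    from .engine import equilibrium_elevation, spin_up

    model = model if model is not None else make_model(spec)
    hc = MSLHindcast()
    if spec.z0_cm is not None:
        z0 = spec.z0_cm
    else:
        # site the core where a long-established marsh sits: in dynamic
        # equilibrium with the mean historic SLR rate over the core window
        r_mean = (hc(float(years)) - hc(float(max(years - 100, 0)))) / min(years, 100)
        z0 = equilibrium_elevation(model, r_mean)
    col, state, _ = spin_up(model, z0)
    start = int(col.deposition_year[0]) + 1
    slr = np.diff(hc(np.arange(years + 1, dtype=float)))
    traj = model.run_years(
        col,
        state,
        C_by_year=np.full(years, spec.C_true_mg_l),
        slr_by_year=slr,
        scaler=spec.scaler_true,
        start_year=start,
    )
    # realized 50-yr accretion: burial depth of the surface of 50 yr ago
    idx = np.where(col.deposition_year <= start + years - 1 - 50)[0]
    depth50 = float(col.depth_tops[idx[0]]) if idx.size else col.total_thickness
    rate = depth50 / 50.0

    profile = col.to_profile(interval_cm=2.0).reset_index(drop=True)
    rng = np.random.default_rng(spec.seed)
    rho = profile["bulk_density_g_cm3"].to_numpy() * rng.lognormal(
        0.0, spec.noise_rho, len(profile)
    )
    o = profile["organic_fraction"].to_numpy() * rng.lognormal(
        0.0, spec.noise_o, len(profile)
    )
    profile["bulk_density_g_cm3"] = rho
    profile["organic_fraction"] = np.clip(o, 0.0, 1.0)

    core = CoreProfile(
        core_id=f"synth_{spec.site}_{spec.seed}",
        intervals=profile,
        accretion_cm_yr=rate,
        surface_z_navd88_m=model.site.msl_navd_m + col.surface_elevation / 100.0,
    )
    manifest = {
        "site": spec.site,
        "C_true_mg_l": spec.C_true_mg_l,
        "scaler_true": spec.scaler_true,
        "z0_cm": float(z0),
        "years": years,
        "noise_rho": spec.noise_rho,
        "noise_o": spec.noise_o,
        "seed": spec.seed,
        "realized_accretion_cm_yr": rate,
        "final_elevation_cm": float(col.surface_elevation),
    }
    return core, manifest


# -- synthetic surveys ----------------------------------------------------

def make_synthetic_survey(
    species: list[SpeciesResponse],
    n_plots: int = 200,
    z_range_cm: tuple[float, float] = (-50.0, 200.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a vegetation transect survey: plots at uniform random
    elevations, presence drawn Bernoulli(S_true(z)) per species, cover
    proportional to suitability with beta-like noise."""
    if n_plots < 50:
        raise ValueError("need at least 50 plots for a usable survey")
    rng = np.random.default_rng(seed)
    z = rng.uniform(z_range_cm[0], z_range_cm[1], n_plots)
    rows = []
    for pid, zz in enumerate(z):
        for sp in species:
            s = sp.suitability(zz)
            present = rng.random() < s
            cover = float(np.clip(s * rng.uniform(0.5, 1.0), 0.0, 1.0)) if present else 0.0
            rows.append(
                {
                    "plot_id": pid,
                    "z_cm": zz,
                    "species": sp.name,
                    "presence": int(present),
                    "cover": cover,
                }
            )
    return pd.DataFrame(rows)


# -- synthetic DEMs -------------------------------------------------------

def make_synthetic_dem(
    shape: tuple[int, int] = (100, 100),
    mean_m: float = 0.74,
    sd_m: float = 0.37,
    smooth_sigma: float = 5.0,
    nodata_border: int = 3,
    seed: int = 0,
    cellsize: float = 5.0,
) -> AsciiGrid:
    """Spatially smoothed Gaussian random elevation field rescaled to a
    target mean/SD (defaults emulate a mid-elevation marsh hypsometry),
    with a nodata border ring to exercise masking."""
    if min(shape) <= 2 * nodata_border:
        raise ValueError("shape too small for the nodata border")
    rng = np.random.default_rng(seed)
    field_ = gaussian_filter(rng.standard_normal(shape), smooth_sigma)
    field_ = (field_ - field_.mean()) / field_.std()
    dem = mean_m + sd_m * field_
    # renormalize interior stats after cutting the border
    if nodata_border > 0:
        dem[:nodata_border, :] = np.nan
        dem[-nodata_border:, :] = np.nan
        dem[:, :nodata_border] = np.nan
        dem[:, -nodata_border:] = np.nan
    interior = dem[np.isfinite(dem)]
    dem = np.where(
        np.isfinite(dem),
        mean_m + sd_m * (dem - interior.mean()) / interior.std(),
        np.nan,
    )
    return AsciiGrid(data=dem, cellsize=cellsize)
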