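"""Annual soil-cohort bookkeeping for tidal-marsh accretion modelling.

The marsh soil is represented as a stack of annual cohorts, newest at the
surface. Each cohort tracks four mass pools per unit area (g/cm²): mineral
sediment, labile organic matter, refractory organic matter, and live roots.
Cohort volume follows from an ideal mixing model for organic and mineral
sediments, so down-core decomposition raises bulk density and shrinks the
cohort — compaction emerges rather than being imposed.

Units are cm, g/cm², g/cm³ throughout; conversions to g m⁻² yr⁻¹ happen
only at reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MixingModel",
    "DecompParams",
    "RootParams",
    "Cohort",
    "SoilColumn",
    "bulk_density",
    "cohort_thickness",
    "labile_remaining",
    "apply_annual_decomposition",
    "split_organic_input",
    "refractory_ratio",
    "distribute_root_growth",
    "turnover_live_roots",
    "erode_mass",
    "annual_elevation_step",
]

#: cohorts with less total mass than this (g/cm²) are pruned
MASS_EPS = 1e-12


@dataclass(frozen=True)
class MixingModel:
    """Ideal two-component mixing model for soil bulk density.

    ``k1`` is the self-packing density of pure organic matter and ``k2``
    that of pure mineral sediment (both g/cm³); bulk density interpolates
    harmonically between them with organic mass fraction.
    """

    k1: float = 0.0823
    k2: float = 1.876

    def __post_init__(self) -> None:
        if not (0.0 < self.k1 < self.k2):
            raise ValueError(f"require 0 < k1 < k2, got k1={self.k1}, k2={self.k2}")


@dataclass(frozen=True)
class DecompParams:
    """Age- and depth-dependent labile decomposition parameters.

    ``A`` holds the annual decomposable fraction for age classes 1, 2 and
    3+ years; ``k_decomp`` (1/cm) attenuates decomposition with burial
    depth; ``refractory_r`` is the fraction of fresh organic input routed
    to the refractory (non-decomposing) pool.
    """

    A: tuple[float, float, float] = (0.69, 0.91, 0.94)
    A_sd: float = 0.05
    k_decomp: float = 0.05
    refractory_r: float = 0.662

    def __post_init__(self) -> None:
        if len(self.A) != 3 or not all(0.0 < a < 1.0 for a in self.A):
            raise ValueError(f"each A must lie in (0,1): {self.A}")
        if not 0.0 <= self.refractory_r <= 1.0:
            raise ValueError(f"refractory_r must lie in [0,1]: {self.refractory_r}")


@dataclass(frozen=True)
class RootParams:
    """Belowground allocation profile.

    ``r2`` (1/cm) is the exponential decay rate of root input with depth,
    ``root_zone_cm`` truncates the profile, and ``live_density`` (g/cm³)
    is the packing density of live roots used for their volume
    contribution (the mixing model applies only to mineral and dead
    organic matter).
    """

    r2: float = 0.1
    root_zone_cm: float = 30.0
    live_density: float = 0.2

    def __post_init__(self) -> None:
        if self.r2 <= 0:
            raise ValueError("r2 must be positive")


@dataclass
class Cohort:
    """Single annual soil layer (view used at the API edge; the column
    itself stores arrays)."""

    deposition_year: int
    mineral_mass: float
    labile_om: float
    refractory_om: float
    live_root: float
    depth_top: float = 0.0

    @property
    def total_mass(self) -> float:
        return self.mineral_mass + self.labile_om + self.refractory_om + self.live_root

    @property
    def organic_fraction(self) -> float:
        tot = self.total_mass
        if tot <= 0:
            return 0.0
        return (self.labile_om + self.refractory_om + self.live_root) / tot


def bulk_density(organic_fraction, mix: MixingModel):
    """Bulk density (g/cm³) of a soil mixture with organic mass fraction ``o``.

    rho = 1 / (o/k1 + (1-o)/k2); bounded in [k1, k2] and strictly
    decreasing in o.
    """
    o = np.asarray(organic_fraction, dtype=float)
    if np.any(o < 0.0) or np.any(o > 1.0):
        raise ValueError("organic fraction outside [0, 1]")
    rho = 1.0 / (o / mix.k1 + (1.0 - o) / mix.k2)
    return float(rho) if np.isscalar(organic_fraction) else rho


def cohort_thickness(c: Cohort, mix: MixingModel) -> float:
    """Thickness (cm) of a cohort: total mass over mixing-model density."""
    tot = c.total_mass
    if tot <= MASS_EPS:
        return 0.0
    return tot / bulk_density(c.organic_fraction, mix)


class SoilColumn:
    """Stack of annual soil cohorts, index 0 at the surface.

    ``surface_elevation`` is tracked in cm relative to the *current* local
    MSL and is advanced once per model year by :func:`annual_elevation_step`.
    """

    __slots__ = (
        "deposition_year",
        "mineral",
        "labile",
        "refractory",
        "live_root",
        "mix",
        "surface_elevation",
        "live_root_density",
    )

    def __init__(
        self,
        mix: MixingModel | None = None,
        surface_elevation: float = 0.0,
        live_root_density: float = 0.2,
    ) -> None:
        self.mix = mix if mix is not None else MixingModel()
        self.live_root_density = float(live_root_density)
        self.deposition_year = np.empty(0, dtype=np.int64)
        self.mineral = np.empty(0, dtype=float)
        self.labile = np.empty(0, dtype=float)
        self.refractory = np.empty(0, dtype=float)
        self.live_root = np.empty(0, dtype=float)
        self.surface_elevation = float(surface_elevation)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_cohorts(
        cls,
        cohorts: list[Cohort],
        mix: MixingModel | None = None,
        surface_elevation: float = 0.0,
    ) -> "SoilColumn":
        col = cls(mix=mix, surface_elevation=surface_elevation)
        if cohorts:
            years = [c.deposition_year for c in cohorts]
            if any(b >= a for a, b in zip(years, years[1:])):
                raise ValueError("cohorts must be strictly ordered, newest first")
            col.deposition_year = np.array(years, dtype=np.int64)
            col.mineral = np.array([c.mineral_mass for c in cohorts], float)
            col.labile = np.array([c.labile_om for c in cohorts], float)
            col.refractory = np.array([c.refractory_om for c in cohorts], float)
            col.live_root = np.array([c.live_root for c in cohorts], float)
            col._validate()
        return col

    def _validate(self) -> None:
        for name in ("mineral", "labile", "refractory", "live_root"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"negative {name} mass")

    def copy(self) -> "SoilColumn":
        new = SoilColumn(
            mix=self.mix,
            surface_elevation=self.surface_elevation,
            live_root_density=self.live_root_density,
        )
        new.deposition_year = self.deposition_year.copy()
        new.mineral = self.mineral.copy()
        new.labile = self.labile.copy()
        new.refractory = self.refractory.copy()
        new.live_root = self.live_root.copy()
        return new

    # -- derived state ---------------------------------------------------
    def __len__(self) -> int:
        return self.deposition_year.size

    @property
    def total_mass(self) -> np.ndarray:
        return self.mineral + self.labile + self.refractory + self.live_root

    @property
    def organic_mass(self) -> np.ndarray:
        return self.labile + self.refractory + self.live_root

    @property
    def organic_fraction(self) -> np.ndarray:
        tot = self.total_mass
        with np.errstate(invalid="ignore", divide="ignore"):
            o = np.where(tot > 0, self.organic_mass / np.where(tot > 0, tot, 1.0), 0.0)
        return np.clip(o, 0.0, 1.0)

    @property
    def bulk_densities(self) -> np.ndarray:
        return bulk_density(self.organic_fraction, self.mix)

    @property
    def thicknesses(self) -> np.ndarray:
        """Cohort thicknesses: mineral + dead organic matter packed by the
        mixing model, plus live roots at their own packing density."""
        dead = self.mineral + self.labile + self.refractory
        with np.errstate(invalid="ignore", divide="ignore"):
            o_dead = np.where(
                dead > 0,
                (self.labile + self.refractory) / np.where(dead > 0, dead, 1.0),
                0.0,
            )
        th = np.where(
            dead > MASS_EPS,
            dead / bulk_density(np.clip(o_dead, 0.0, 1.0), self.mix),
            0.0,
        )
        return th + self.live_root / self.live_root_density

    @property
    def total_thickness(self) -> float:
        return float(self.thicknesses.sum())

    @property
    def depth_tops(self) -> np.ndarray:
        """Depth (cm below surface) of the top of each cohort."""
        th = self.thicknesses
        return np.concatenate(([0.0], np.cumsum(th)[:-1])) if th.size else th

    @property
    def depth_mids(self) -> np.ndarray:
        th = self.thicknesses
        return self.depth_tops + 0.5 * th if th.size else th

    def cohort(self, i: int) -> Cohort:
        return Cohort(
            deposition_year=int(self.deposition_year[i]),
            mineral_mass=float(self.mineral[i]),
            labile_om=float(self.labile[i]),
            refractory_om=float(self.refractory[i]),
            live_root=float(self.live_root[i]),
            depth_top=float(self.depth_tops[i]),
        )

    # -- mutation --------------------------------------------------------
    def add_surface_cohort(
        self,
        year: int,
        mineral: float = 0.0,
        labile: float = 0.0,
        refractory: float = 0.0,
        live_root: float = 0.0,
    ) -> None:
        if len(self) and year <= self.deposition_year[0]:
            raise ValueError("new cohort year must exceed the current surface year")
        self.deposition_year = np.concatenate(([year], self.deposition_year))
        self.mineral = np.concatenate(([mineral], self.mineral))
        self.labile = np.concatenate(([labile], self.labile))
        self.refractory = np.concatenate(([refractory], self.refractory))
        self.live_root = np.concatenate(([live_root], self.live_root))

    def prune(self) -> None:
        """Drop cohorts whose total mass has fallen below ``MASS_EPS``."""
        keep = self.total_mass >= MASS_EPS
        if not keep.all():
            for name in ("deposition_year", "mineral", "labile", "refractory", "live_root"):
                setattr(self, name, getattr(self, name)[keep])

    # -- export ----------------------------------------------------------
    def to_profile(self, interval_cm: float = 2.0) -> pd.DataFrame:
        """Resample the column into regular depth intervals.

        Returns the same tabular schema as soil-core input data
        (depth_top_cm, depth_bottom_cm, bulk_density_g_cm3,
        organic_fraction), with cohort mass spread uniformly over each
        cohort's own span.
        """
        th = self.thicknesses
        total = th.sum()
        if total <= 0:
            return pd.DataFrame(
                columns=[
                    "depth_top_cm",
                    "depth_bottom_cm",
                    "bulk_density_g_cm3",
                    "organic_fraction",
                ]
            )
        tops = self.depth_tops
        bots = tops + th
        n_bins = int(math.ceil(total / interval_cm))
        edges = np.arange(n_bins + 1) * interval_cm
        min_bin = np.zeros(n_bins)
        org_bin = np.zeros(n_bins)
        om = self.organic_mass
        for i in range(len(self)):
            if th[i] <= 0:
                continue
            lo = np.clip(edges[:-1], tops[i], bots[i])
            hi = np.clip(edges[1:], tops[i], bots[i])
            frac = np.maximum(hi - lo, 0.0) / th[i]
            min_bin += frac * self.mineral[i]
            org_bin += frac * om[i]
        widths = np.minimum(edges[1:], total) - edges[:-1]
        mass = min_bin + org_bin
        ok = (mass > MASS_EPS) & (widths > 1e-9)
        rho = np.where(ok, mass / np.where(widths > 0, widths, 1.0), np.nan)
        o = np.where(ok, org_bin / np.where(mass > 0, mass, 1.0), np.nan)
        return pd.DataFrame(
            {
                "depth_top_cm": edges[:-1],
                "depth_bottom_cm": edges[:-1] + widths,
                "bulk_density_g_cm3": rho,
                "organic_fraction": o,
            }
        )[ok]


# -- decomposition -------------------------------------------------------

def labile_remaining(age_class: int, depth, p: DecompParams):
    """Fraction of labile organic matter surviving one year of
    decomposition for a cohort of the given age class at the given burial
    depth (cm): 1 − A(age)·exp(−k·d). Deeper and older material loses less.
    """
    idx = int(age_class)
    if idx < 1:
        raise ValueError("age class must be >= 1")
    a = p.A[min(idx, 3) - 1]
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be non-negative")
    out = 1.0 - a * np.exp(-p.k_decomp * d)
    return float(out) if np.isscalar(depth) else out


def apply_annual_decomposition(
    col: SoilColumn, p: DecompParams, current_year: int
) -> float:
    """Decompose every cohort's labile pool for one year, in place.

    Age class is 1 for the cohort deposited this model year, 2 for last
    year's, 3+ otherwise; depth is the cohort mid-depth. Mineral,
    refractory, and live-root pools are untouched. Returns the total mass
    lost (g/cm²).
    """
    if len(col) == 0:
        return 0.0
    age = current_year - col.deposition_year + 1
    cls = np.clip(age, 1, 3)
    a = np.asarray(p.A, dtype=float)[cls - 1]
    remain = 1.0 - a * np.exp(-p.k_decomp * col.depth_mids)
    lost = float(np.sum(col.labile * (1.0 - remain)))
    col.labile = col.labile * remain
    return lost


def refractory_ratio(om_bottom: float, om_top: float) -> float:
    """Refractory fraction r from the ratio of organic content at the
    bottom of the core to the top (surviving fraction after long burial)."""
    if om_top <= 0:
        raise ValueError("om_top must be positive")
    return float(np.clip(om_bottom / om_top, 0.0, 1.0))


def split_organic_input(gross_om: float, p: DecompParams) -> tuple[float, float]:
    """Split fresh organic input into (labile, refractory) by the
    refractory fraction r."""
    if gross_om < 0:
        raise ValueError("gross organic input must be non-negative")
    refractory = p.refractory_r * gross_om
    return gross_om - refractory, refractory


# -- roots ---------------------------------------------------------------

def _root_weights(col: SoilColumn, r2: float, root_zone_cm: float) -> np.ndarray:
    """Allocation weights ∝ ∫ exp(−r2·d) dd across each cohort's depth
    span, truncated at the root zone; normalized to sum to 1 (zeros if no
    cohort intersects the root zone)."""
    th = col.thicknesses
    tops = col.depth_tops
    bots = np.minimum(tops + th, root_zone_cm)
    tops = np.minimum(tops, root_zone_cm)
    with np.errstate(over="ignore"):
        w = np.exp(-r2 * tops) - np.exp(-r2 * bots)
    w = np.maximum(w, 0.0)
    s = w.sum()
    return w / s if s > 0 else w


def distribute_root_growth(
    col: SoilColumn,
    total_root_om: float,
    root: RootParams,
    year: int | None = None,
) -> None:
    """Allocate the year's belowground production into the live-root
    pools of the cohorts, with exponentially decaying weights in depth.

    The live pool is the standing stock of this root growth; it joins
    the dead organic pools at the next annual turnover (see
    :func:`turnover_live_roots`). An empty column receives a new surface
    cohort."""
    if total_root_om < 0:
        raise ValueError("root input must be non-negative")
    if total_root_om == 0:
        return
    if len(col) == 0:
        col.add_surface_cohort(year if year is not None else 0, live_root=total_root_om)
        return
    w = _root_weights(col, root.r2, root.root_zone_cm)
    if w.sum() <= 0:
        w = np.zeros_like(w)
        w[0] = 1.0
    col.live_root = col.live_root + total_root_om * w


def turnover_live_roots(col: SoilColumn, p: DecompParams) -> float:
    """Annual root mortality: the whole live-root standing stock dies
    into the labile/refractory split, in place. Returns the mass turned
    over (g/cm²)."""
    turned = float(col.live_root.sum())
    if turned > 0:
        col.labile = col.labile + (1.0 - p.refractory_r) * col.live_root
        col.refractory = col.refractory + p.refractory_r * col.live_root
        col.live_root = np.zeros_like(col.live_root)
    return turned


# -- erosion & the annual budget ----------------------------------------

def erode_mass(col: SoilColumn, mass: float) -> float:
    """Strip ``mass`` g/cm² from the top of the column, removing each
    surface cohort's pools proportionally. Returns the mass actually
    removed (limited by what is there)."""
    removed = 0.0
    while mass > MASS_EPS and len(col):
        tot = float(col.total_mass[0])
        if tot <= MASS_EPS:
            col.prune()
            continue
        take = min(mass, tot)
        f = 1.0 - take / tot
        col.mineral[0] *= f
        col.labile[0] *= f
        col.refractory[0] *= f
        col.live_root[0] *= f
        removed += take
        mass -= take
        if f <= 0:
            col.prune()
    return removed


def annual_elevation_step(
    col: SoilColumn,
    mar_vol: float,
    oar_vol: float,
    decomp_vol: float,
    slr_cm: float,
) -> float:
    """Advance the surface elevation by the annual budget
    ΔE = MAR + OAR − DECOMP − SLR (all in cm of thickness change).

    The engine measures the three volume components as thickness
    differences over the year's deposit/decompose sequence (which appends
    the year's new cohort), so closure is exact by telescoping. Returns
    the new elevation (cm relative to MSL).
    """
    col.surface_elevation += mar_vol + oar_vol - decomp_vol - slr_cm
    return col.surface_elevation
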