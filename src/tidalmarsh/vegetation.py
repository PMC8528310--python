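"""Species-transition community model.

Plant cover evolves by suitability-weighted logistic growth with a shared
carrying capacity (no explicit competition terms: the elevation
suitability function of each species, estimated from field occurrence,
already folds in biotic limits). Production follows a second-order
polynomial in percent time inundated, fitted to marsh-organ biomass
experiments; salinization applies a linear biomass penalty. Soil carbon
accumulation assumes soil organic matter is 42% carbon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpeciesResponse",
    "CommunityState",
    "SalinityScenario",
    "CARBON_FRACTION",
    "MUDFLAT_COVER_THRESHOLD",
    "SEEDING_FLOOR",
    "suitability_from_survey",
    "step_cover",
    "organic_production",
    "apply_salinity",
    "carbon_accumulation",
    "classify_state",
]

#: carbon content of soil organic matter (mass fraction)
CARBON_FRACTION = 0.42
#: total plant cover below which the surface is classed as mudflat
MUDFLAT_COVER_THRESHOLD = 0.20
#: minimum cover seeded where a species' suitability becomes positive
SEEDING_FLOOR = 1e-3
#: sub-steps per year for the cover ODE (keeps Euler stable to r1 ~ 2/yr)
_SUBSTEPS = 4


@dataclass
class SpeciesResponse:
    """One species' elevation suitability and productivity response.

    ``suitability_z_cm`` / ``suitability_s`` define a piecewise-linear
    suitability S(z) in [0, 1] over elevation (cm, MSL), zero outside the
    given span. ``poly`` = (a0, a1, a2) predicts total dry biomass
    (g m⁻² yr⁻¹) from percent time inundated, clamped at zero. ``r1`` is
    the maximum cover growth rate (1/yr) and ``o_scale`` a site-calibrated
    organic-production scaler.
    """

    name: str
    suitability_z_cm: np.ndarray
    suitability_s: np.ndarray
    poly: tuple[float, float, float]
    r1: float = 1.0
    o_scale: float = 1.0

    def __post_init__(self) -> None:
        self.suitability_z_cm = np.asarray(self.suitability_z_cm, dtype=float)
        self.suitability_s = np.asarray(self.suitability_s, dtype=float)
        if self.suitability_z_cm.shape != self.suitability_s.shape:
            raise ValueError("suitability z and S must have matching shapes")
        if np.any(self.suitability_s < 0) or np.any(self.suitability_s > 1):
            raise ValueError("suitability values must lie in [0, 1]")
        if self.r1 <= 0:
            raise ValueError("r1 must be positive")

    def suitability(self, z_cm: float) -> float:
        """S(z) in [0, 1]; zero outside the tabulated span."""
        z = self.suitability_z_cm
        if z_cm < z[0] or z_cm > z[-1]:
            return 0.0
        return float(np.interp(z_cm, z, self.suitability_s))

    def biomass(self, pct_inundated: float) -> float:
        """Total dry biomass (g m⁻² yr⁻¹) at a percent-time-inundated,
        clamped at zero."""
        a0, a1, a2 = self.poly
        i = float(pct_inundated)
        return max(0.0, a0 + a1 * i + a2 * i * i)


@dataclass
class CommunityState:
    """Fractional cover per species; total never exceeds 1."""

    cover: np.ndarray

    def __post_init__(self) -> None:
        self.cover = np.asarray(self.cover, dtype=float)
        if np.any(self.cover < 0) or np.any(self.cover > 1):
            raise ValueError("cover fractions must lie in [0, 1]")
        if self.cover.sum() > 1.0 + 1e-9:
            raise ValueError("total cover exceeds 1")

    @property
    def total(self) -> float:
        return float(self.cover.sum())

    def copy(self) -> "CommunityState":
        return CommunityState(self.cover.copy())


@dataclass(frozen=True)
class SalinityScenario:
    """Linear salinization ramp (PSU per decade) and its biomass penalty
    omega (fractional biomass loss per PSU)."""

    ramp_psu_per_decade: float = 0.0
    omega: float = 0.027
    omega_sd: float = 0.008

    def __post_init__(self) -> None:
        if self.ramp_psu_per_decade < 0 or self.omega < 0:
            raise ValueError("ramp and omega must be non-negative")

    def delta_psu(self, t_years: float) -> float:
        return self.ramp_psu_per_decade * t_years / 10.0


def suitability_from_survey(
    z_presences_cm: np.ndarray,
    z_grid_cm: np.ndarray,
    bandwidth_cm: float | None = None,
) -> np.ndarray:
    """Estimate an elevation suitability curve from plot elevations where
    a species was present: a Gaussian kernel density over elevation,
    normalized to a maximum of 1."""
    from scipy.stats import gaussian_kde

    z = np.asarray(z_presences_cm, dtype=float)
    if z.size < 3:
        raise ValueError("need at least 3 presence elevations")
    if np.ptp(z) < 1e-9:
        # degenerate support: a narrow triangular bump at the single elevation
        s = np.clip(1.0 - np.abs(np.asarray(z_grid_cm) - z[0]) / 5.0, 0.0, 1.0)
        return s
    kde = gaussian_kde(z, bw_method=bandwidth_cm / z.std(ddof=1) if bandwidth_cm else None)
    s = kde(np.asarray(z_grid_cm, dtype=float))
    return s / s.max()


def step_cover(
    state: CommunityState,
    z_cm: float,
    species: list[SpeciesResponse],
    dt: float = 1.0,
) -> CommunityState:
    """Advance community cover one timestep (default 1 yr).

    Each species grows logistically at rate r1·S(z) toward the shared
    carrying capacity (total cover 1); where S(z)=0 it decays at rate r1.
    A seeding floor lets species colonize newly suitable elevations.
    Integration is midpoint (RK2) over sub-steps, clamped to the cover
    invariants.
    """
    p = state.cover.copy()
    s = np.array([sp.suitability(z_cm) for sp in species])
    r1 = np.array([sp.r1 for sp in species])
    # colonization of suitable, unoccupied ground
    p = np.where((s > 0) & (p < SEEDING_FLOOR), SEEDING_FLOOR, p)

    def deriv(q: np.ndarray) -> np.ndarray:
        crowding = max(0.0, 1.0 - q.sum())
        return np.where(s > 0, q * r1 * s * crowding, -q * r1)

    h = dt / _SUBSTEPS
    for _ in range(_SUBSTEPS):
        mid = np.clip(p + 0.5 * h * deriv(p), 0.0, 1.0)
        p = np.clip(p + h * deriv(mid), 0.0, 1.0)
        total = p.sum()
        if total > 1.0:
            p *= 1.0 / total
    return CommunityState(p)


def organic_production(
    z_cm: float,
    state: CommunityState,
    inundation_frac: float,
    species: list[SpeciesResponse],
) -> float:
    """Gross soil organic matter input (g m⁻² yr⁻¹): cover-weighted sum of
    each species' clamped productivity polynomial at the surface's percent
    time inundated, times its calibrated scaler."""
    if len(species) != state.cover.size:
        raise ValueError("state and species set sizes differ")
    pct = 100.0 * inundation_frac
    return float(
        sum(
            p * sp.o_scale * sp.biomass(pct)
            for p, sp in zip(state.cover, species)
        )
    )


def apply_salinity(production: float, t_years: float, s: SalinityScenario) -> float:
    """Reduce production by the linear salinity penalty
    B·(1 − ω·ΔPSU(t)), floored at zero."""
    if t_years < 0:
        raise ValueError("time must be non-negative")
    return max(0.0, production * (1.0 - s.omega * s.delta_psu(t_years)))


def carbon_accumulation(retained_som_g_m2_yr: float) -> float:
    """Carbon accumulation rate (g C m⁻² yr⁻¹) from net annual soil
    organic matter retention, at 42% carbon content."""
    return CARBON_FRACTION * retained_som_g_m2_yr


def classify_state(state: CommunityState) -> str:
    """'mudflat' if total cover is below 20%, else 'vegetated'."""
    return "mudflat" if state.total < MUDFLAT_COVER_THRESHOLD else "vegetated"
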