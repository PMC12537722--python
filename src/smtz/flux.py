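"""Sulfate gradient fitting, depth of no sulfate, and diffusive fluxes.

Porewater sulfate in these sediments decreases roughly linearly from the
seafloor to the depth of no sulfate (DNS), the horizon where anaerobic
oxidation of methane and organoclastic sulfate reduction have consumed it
all.  A linear regression over that interval gives dC/dx for Fick's first
law; the free-solution diffusion coefficient is reduced for tortuosity with
the logarithmic correction theta^2 = 1 - ln(phi^2).  Cores whose sulfate
profile is clearly non-linear violate the steady-state diffusion assumption
and are excluded before bay/season averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PorewaterProfile",
    "LinearFit",
    "FluxResult",
    "fit_sulfate_gradient",
    "depth_of_no_sulfate",
    "sulfate_diffusion_coefficient",
    "sediment_diffusivity",
    "diffusive_flux",
    "apply_linearity_exclusion",
    "core_flux",
    "bay_season_flux_summary",
]

# (cm^2 s^-1) * (mM cm^-1) -> mmol m^-2 d^-1:
#   mM cm^-1 = 1e-3 mmol cm^-4, x 86400 s d^-1, x 1e4 cm^2 m^-2
_UNIT_FACTOR = 1e-3 * 86400.0 * 1e4  # = 8.64e5


@dataclass
class PorewaterProfile:
    """One core's depth-indexed porewater analyte concentrations.

    depths are slice midpoints in cm below seafloor (positive down, strictly
    increasing); analytes maps analyte name -> concentration series (mM)
    aligned with depths.
    """

    site: str
    bay: str
    season: str
    depths: np.ndarray
    analytes: dict[str, np.ndarray]
    porosity: float = 0.8

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.size == 0:
            raise ValueError("profile needs at least one depth")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError(f"porosity must be in (0, 1), got {self.porosity}")
        self.analytes = {k: np.asarray(v, dtype=float) for k, v in self.analytes.items()}
        for name, values in self.analytes.items():
            if values.shape != self.depths.shape:
                raise ValueError(f"analyte {name!r} length does not match depths")
            if np.any(values < 0):
                raise ValueError(f"analyte {name!r} has negative concentrations")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.site, self.bay, self.season)


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of sulfate concentration (mM) on depth (cm)."""

    slope: float  # mM cm^-1
    intercept: float  # mM at 0 cm
    r_squared: float
    n_points: int
    depth_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("linear fit requires at least 3 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of range: {self.r_squared}")


@dataclass
class FluxResult:
    """Per-core flux computation: fit, DNS, diffusivities, flux, inclusion."""

    site: str
    bay: str
    season: str
    fit: LinearFit
    dns: float | None  # cm
    d0: float  # cm^2 s^-1
    ds: float  # cm^2 s^-1
    flux: float  # mmol m^-2 d^-1, positive downward
    included: bool
    exclusion_reason: str | None = None


def fit_sulfate_gradient(profile: PorewaterProfile) -> LinearFit:
    """Fit the linear sulfate gradient of one core.

    The regression window runs from the depth of maximum sulfate concentration
    (so a winter subsurface peak shifts the window start below a depressed
    surface layer) down through the contiguous run of strictly positive
    concentrations; the first zero ends the window.  The fit is then iterated:
    the x-intercept of each fit trims window points deeper than the implied
    depletion depth and the line is refit until the window stabilises, so the
    gradient is estimated strictly between the seafloor (or subsurface peak)
    and the depth of no sulfate.  Without this trimming, near-zero readings
    just below the depletion horizon flatten the fitted gradient.
    """
    if "sulfate" not in profile.analytes:
        raise ValueError(f"profile {profile.key} has no sulfate series")
    sulfate = profile.analytes["sulfate"]
    if np.all(sulfate == 0):
        raise ValueError(f"profile {profile.key}: all sulfate concentrations are zero")
    start = int(np.argmax(sulfate))
    stop = start
    while stop + 1 < sulfate.size and sulfate[stop + 1] > 0:
        stop += 1
    x, y = profile.depths[start : stop + 1], sulfate[start : stop + 1]
    if x.size < 3:
        raise ValueError(
            f"profile {profile.key}: only {x.size} usable sulfate points in the "
            "regression window (need >= 3)"
        )
    res = stats.linregress(x, y)
    for _ in range(20):  # trim to the implied depletion depth until stable
        if res.slope >= 0:
            break
        dns = -res.intercept / res.slope
        mask = x <= dns
        if mask.all() or mask.sum() < 3:
            break
        x, y = x[mask], y[mask]
        res = stats.linregress(x, y)
    # constant concentrations: zero variance makes r undefined; report 0 (no trend)
    r_squared = 0.0 if np.isnan(res.rvalue) else min(float(res.rvalue**2), 1.0)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r_squared,
        n_points=int(x.size),
        depth_window=(float(x[0]), float(x[-1])),
    )


def depth_of_no_sulfate(fit: LinearFit) -> float:
    """Depth (cm) where the regression line reaches zero sulfate (x-intercept)."""
    if fit.slope >= 0:
        raise ValueError(
            "sulfate does not decrease with depth (slope >= 0); no depletion depth"
        )
    return -fit.intercept / fit.slope


def sulfate_diffusion_coefficient(
    temperature_c: float, m0: float = 4.88, m1: float = 0.232
) -> float:
    """Free-solution sulfate diffusion coefficient D0 (cm^2 s^-1).

    Linear-in-temperature parameterization d0 = (m0 + m1*T) * 1e-6 with default
    coefficients from standard seawater diffusion tabulations; T in degC.
    """
    if not -2.0 <= temperature_c <= 40.0:
        warnings.warn(
            f"temperature {temperature_c} degC outside the calibrated range [-2, 40]",
            stacklevel=2,
        )
    return (m0 + m1 * temperature_c) * 1e-6


def sediment_diffusivity(d0: float, porosity: float) -> float:
    """Tortuosity-corrected sediment diffusivity Ds = D0 / (1 - ln(phi^2))."""
    if not 0.0 < porosity < 1.0:
        raise ValueError(f"porosity must be in (0, 1), got {porosity}")
    return d0 / (1.0 - math.log(porosity**2))


def diffusive_flux(
    fit: LinearFit,
    ds: float,
    porosity: float,
    include_porosity_factor: bool = True,
) -> float:
    """Diffusive sulfate flux J (mmol m^-2 d^-1), positive downward.

    Fick's first law on the fitted gradient, J = -phi * Ds * dC/dx in the
    standard diagenetic form; ``include_porosity_factor=False`` drops phi for
    the bare J = -Ds * dC/dx convention.  A negative slope (sulfate consumed
    at depth) gives a positive downward flux, whose magnitude doubles as the
    AOM-implied upward methane flux.
    """
    phi = porosity if include_porosity_factor else 1.0
    return -phi * ds * fit.slope * _UNIT_FACTOR


def apply_linearity_exclusion(
    fit: LinearFit, r2_threshold: float = 0.90
) -> tuple[bool, str | None]:
    """Flag cores whose sulfate profile is too non-linear for a diffusive fit."""
    if fit.r_squared >= r2_threshold:
        return True, None
    return False, (
        f"non-linear sulfate profile (R^2 = {fit.r_squared:.3f} < {r2_threshold:.2f})"
    )


def core_flux(
    profile: PorewaterProfile,
    temperature_c: float,
    m0: float = 4.88,
    m1: float = 0.232,
    r2_threshold: float = 0.90,
    include_porosity_factor: bool = True,
) -> FluxResult:
    """Full per-core chain: fit, DNS, D0, Ds, flux, linearity exclusion."""
    fit = fit_sulfate_gradient(profile)
    d0 = sulfate_diffusion_coefficient(temperature_c, m0=m0, m1=m1)
    ds = sediment_diffusivity(d0, profile.porosity)
    flux = diffusive_flux(fit, ds, profile.porosity, include_porosity_factor)
    included, reason = apply_linearity_exclusion(fit, r2_threshold)
    dns: float | None
    if fit.slope < 0:
        dns = depth_of_no_sulfate(fit)
    else:
        dns = None
        included, reason = False, "sulfate does not decrease with depth"
    return FluxResult(
        site=profile.site,
        bay=profile.bay,
        season=profile.season,
        fit=fit,
        dns=dns,
        d0=d0,
        ds=ds,
        flux=flux,
        included=included,
        exclusion_reason=reason,
    )


def bay_season_flux_summary(results: list[FluxResult]) -> pd.DataFrame:
    """Mean flux and mean DNS per (bay, season) over included cores.

    Groups with no included core yield NaN means with n_included = 0 rather
    than being dropped.
    """
    if not results:
        raise ValueError("no flux results to summarize")
    rows = []
    frame = pd.DataFrame(
        {
            "bay": [r.bay for r in results],
            "season": [r.season for r in results],
            "flux": [r.flux for r in results],
            "dns": [r.dns for r in results],
            "included": [r.included for r in results],
        }
    )
    for (bay, season), group in frame.groupby(["bay", "season"], sort=True):
        used = group[group["included"]]
        rows.append(
            {
                "bay": bay,
                "season": season,
                "n_cores": int(len(group)),
                "n_included": int(len(used)),
                "mean_flux_mmol_m2_d": float(used["flux"].mean()) if len(used) else float("nan"),
                "mean_dns_cm": float(used["dns"].mean()) if len(used) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
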