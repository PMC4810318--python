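"""Relativistic kinematics, Bethe stopping power, and range-energy tables.

The energy-loss model is the uncorrected Bethe formula for a bare nucleus of
charge Z and velocity beta in a medium with mean excitation energy I:

    S = K (Z/A)_mat (Z_proj/beta)^2 [ ln(2 m_e c^2 beta^2 gamma^2 / I) - beta^2 ]

with S the mass stopping power in MeV cm^2 g^-1.  Density-effect and shell
corrections are deliberately omitted; the model is intended for kinetic
energies of roughly 1 MeV/nuc and above, with the region of interest for
space and therapy applications starting near 10 MeV/nuc.  Below the
1 MeV/nuc validity floor the residual range is taken as a fixed small
constant scaled by A/Z^2 rather than extrapolating the formula into a region
where it is unphysical.

Ranges follow from integrating the reciprocal stopping power (continuous
slowing-down approximation).  Because the mass stopping power at a given
energy per nucleon depends on the projectile only through Z^2, the range of
any ion is (A/Z^2) times the proton range at the same energy per nucleon —
a property the implementation inherits exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.integrate import quad

from .constants import CONSTANTS, MEV_CM2_G_TO_KEV_UM
from .materials import Material, WATER

#: Lowest energy per nucleon (MeV/nuc) at which the Bethe formula is evaluated.
ENERGY_FLOOR = 1.0

#: Residual areal range (g cm^-2) assigned to a proton below the floor;
#: scaled by A/Z^2 for other ions.
SUBFLOOR_RANGE = 0.01


class StoppedParticle(float):
    """Sentinel returned by :func:`energy_at_depth` for a stopped ion.

    Compares equal to 0.0 so downstream arithmetic stays well defined.
    """

    __slots__ = ()

    def __new__(cls) -> "StoppedParticle":
        return super().__new__(cls, 0.0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "StoppedParticle(0.0)"


STOPPED = StoppedParticle()


@dataclass(frozen=True)
class IonState:
    """A projectile or fragment: charge, mass number, kinetic energy.

    ``energy_per_nucleon`` is in MeV/nuc.
    """

    z_proj: int
    a_proj: int
    energy_per_nucleon: float

    def __post_init__(self) -> None:
        if self.z_proj < 1:
            raise ValueError("z_proj must be >= 1")
        if self.a_proj < self.z_proj:
            raise ValueError("a_proj must be >= z_proj")
        if self.energy_per_nucleon < 0:
            raise ValueError("energy_per_nucleon must be >= 0")

    def with_energy(self, energy_per_nucleon: float) -> "IonState":
        return IonState(self.z_proj, self.a_proj, energy_per_nucleon)


# --------------------------------------------------------------------------
# Kinematics
# --------------------------------------------------------------------------

def gamma_from_energy(energy_per_nucleon):
    """Lorentz factor for a given kinetic energy per nucleon (MeV/nuc)."""
    e = np.asarray(energy_per_nucleon, dtype=float)
    if np.any(e < 0):
        raise ValueError("energy must be >= 0")
    return 1.0 + e / CONSTANTS.nucleon_rest_energy


def beta_from_energy(energy_per_nucleon):
    """Speed relative to c for a kinetic energy per nucleon (MeV/nuc).

    Strictly increasing in energy; 0 at rest, asymptotically < 1.
    """
    g = gamma_from_energy(energy_per_nucleon)
    b2 = 1.0 - 1.0 / (g * g)
    out = np.sqrt(np.maximum(b2, 0.0))
    return float(out) if np.isscalar(energy_per_nucleon) else out


def momentum_per_nucleon(energy_per_nucleon):
    """Momentum per nucleon, MeV/c: p = sqrt(T (T + 2 m)).

    The total momentum of an A-nucleon ion at the same velocity is A times
    this value, which is how a 250 MeV/nuc 4He fragment carries roughly
    3 GeV/c of longitudinal momentum.
    """
    e = np.asarray(energy_per_nucleon, dtype=float)
    if np.any(e < 0):
        raise ValueError("energy must be >= 0")
    m = CONSTANTS.nucleon_rest_energy
    out = np.sqrt(e * (e + 2.0 * m))
    return float(out) if np.isscalar(energy_per_nucleon) else out


def energy_from_momentum_per_nucleon(p):
    """Inverse of :func:`momentum_per_nucleon` (MeV/c -> MeV/nuc)."""
    p = np.asarray(p, dtype=float)
    m = CONSTANTS.nucleon_rest_energy
    out = np.sqrt(p * p + m * m) - m
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# Stopping power
# --------------------------------------------------------------------------

def _bethe_bracket(beta2: np.ndarray, i_ev: float) -> np.ndarray:
    gamma2 = 1.0 / (1.0 - beta2)
    arg = 2.0 * CONSTANTS.electron_rest_energy * 1e6 * beta2 * gamma2 / i_ev
    return np.log(arg) - beta2


def stopping_power(ion: IonState, material: Material,
                   energy_per_nucleon=None):
    """Mass stopping power of the ion, MeV cm^2 g^-1.

    This is the *total* energy loss of the ion per unit areal density
    (not per nucleon).  Scales exactly as Z_proj^2 at fixed energy per
    nucleon, and as the mass-fraction-weighted <Z/A> of the medium.

    Raises
    ------
    ValueError
        If the energy is below the 1 MeV/nuc validity floor, where the
        uncorrected formula is meaningless.
    """
    e = ion.energy_per_nucleon if energy_per_nucleon is None \
        else energy_per_nucleon
    e = np.asarray(e, dtype=float)
    if np.any(e < ENERGY_FLOOR):
        raise ValueError(
            f"stopping power requested at {float(np.min(e)):.3g} MeV/nuc, "
            f"below the {ENERGY_FLOOR} MeV/nuc validity floor")
    b = beta_from_energy(e)
    beta2 = b * b
    out = (CONSTANTS.k * material.z_over_a * ion.z_proj ** 2 / beta2
           * _bethe_bracket(beta2, material.mean_excitation_energy))
    return float(out) if out.ndim == 0 else out


def let_water(ion: IonState, energy_per_nucleon=None):
    """LET-infinity in water, keV/um.

    Mass stopping power in water times density (1 g cm^-3), unit-converted.
    """
    s = stopping_power(ion, WATER, energy_per_nucleon)
    return s * WATER.density * MEV_CM2_G_TO_KEV_UM


# --------------------------------------------------------------------------
# Range-energy relation
# --------------------------------------------------------------------------

def _proton_range_quad(energy: float, material: Material,
                       epsrel: float = 1e-8) -> float:
    """CSDA areal range of a proton above the floor, adaptive quadrature."""
    if energy <= ENERGY_FLOOR:
        return 0.0
    proton = IonState(1, 1, energy)

    def integrand(t: float) -> float:
        return 1.0 / stopping_power(proton, material, t)

    val, _ = quad(integrand, ENERGY_FLOOR, energy, epsrel=epsrel, limit=200)
    return val


def csda_range(ion: IonState, material: Material,
               energy_per_nucleon: float | None = None) -> float:
    """Continuous-slowing-down areal range, g cm^-2.

    Computed as (A/Z^2) times the proton range at the same energy per
    nucleon (exact for the Bethe model), plus a small constant sub-floor
    tail for the residual range below the 1 MeV/nuc cutoff.
    """
    e = ion.energy_per_nucleon if energy_per_nucleon is None \
        else energy_per_nucleon
    if e < ENERGY_FLOOR:
        raise ValueError(
            f"range requested at {e:.3g} MeV/nuc, below the validity floor")
    scale = ion.a_proj / ion.z_proj ** 2
    return scale * (_proton_range_quad(e, material) + SUBFLOOR_RANGE)


class RangeEnergyTable:
    """Cached log-grid range-energy relation for one (ion, material) pair.

    Provides fast vectorized range(E) and energy(residual range) lookups
    used heavily by the Monte Carlo transport.  The grid is log-spaced in
    energy from the validity floor to ``e_max``; interpolation is linear in
    (log E, log R), which is accurate to much better than 0.1% at the
    default resolution because R(E) is a smooth near-power-law.
    """

    def __init__(self, ion: IonState, material: Material,
                 e_max: float = 5.0e4, n_grid: int = 2000) -> None:
        self.ion = ion
        self.material = material
        scale = ion.a_proj / ion.z_proj ** 2
        e = np.geomspace(ENERGY_FLOOR, e_max, n_grid)
        proton = IonState(1, 1, e_max)
        inv_s = 1.0 / stopping_power(proton, material, e)
        # cumulative trapezoid of dT/S(T), exact log-grid spacing
        r = np.concatenate(([0.0], np.cumsum(
            0.5 * (inv_s[1:] + inv_s[:-1]) * np.diff(e))))
        self._log_e = np.log(e)
        self._range = scale * (r + SUBFLOOR_RANGE)
        self._log_r = np.log(self._range)
        self.subfloor = scale * SUBFLOOR_RANGE

    def range_of(self, energy_per_nucleon):
        """Areal range (g cm^-2) at the given energy per nucleon."""
        loge = np.log(np.clip(energy_per_nucleon, ENERGY_FLOOR, None))
        out = np.exp(np.interp(loge, self._log_e, self._log_r))
        return float(out) if np.isscalar(energy_per_nucleon) else out

    def energy_of(self, residual_range):
        """Energy per nucleon at a given residual areal range.

        Residual ranges at or below the sub-floor constant map to 0
        (stopped).
        """
        r = np.asarray(residual_range, dtype=float)
        logr = np.log(np.clip(r, self._range[0], None))
        e = np.exp(np.interp(logr, self._log_r, self._log_e))
        e = np.where(r <= self.subfloor, 0.0, e)
        return float(e) if np.isscalar(residual_range) else e


@lru_cache(maxsize=256)
def _cached_table(z: int, a: int, material_key: str,
                  material: Material) -> RangeEnergyTable:
    return RangeEnergyTable(IonState(z, a, ENERGY_FLOOR), material)


def range_table(ion: IonState, material: Material) -> RangeEnergyTable:
    """Cached :class:`RangeEnergyTable` for an ion species in a material."""
    return _cached_table(ion.z_proj, ion.a_proj, material.name, material)


def energy_at_depth(ion: IonState, material: Material, depth: float):
    """Energy per nucleon after traversing ``depth`` g cm^-2.

    Returns the :data:`STOPPED` sentinel (== 0.0) when the depth is at or
    beyond the ion's range.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0.0:
        return ion.energy_per_nucleon
    full = csda_range(ion, material)
    residual = full - depth
    scale = ion.a_proj / ion.z_proj ** 2
    if residual <= scale * SUBFLOOR_RANGE:
        return STOPPED
    # invert R(T) = residual for the proton-equivalent range
    target = residual / scale - SUBFLOOR_RANGE
    lo, hi = ENERGY_FLOOR, ion.energy_per_nucleon
    from scipy.optimize import brentq
    sol = brentq(lambda t: _proton_range_quad(t, material) - target,
                 lo, hi, xtol=1e-10, rtol=1e-12)
    return float(sol)


# --------------------------------------------------------------------------
# Table export
# --------------------------------------------------------------------------

def export_range_table(ion: IonState, material: Material, path: str | Path,
                       energies=None) -> None:
    """Write a CSV of stopping power and range vs energy per nucleon."""
    import pandas as pd

    if energies is None:
        energies = np.geomspace(10.0, 2000.0, 60)
    energies = np.asarray(energies, dtype=float)
    rows = {
        "energy_MeV_per_nuc": energies,
        "stopping_MeV_cm2_g": stopping_power(ion, material, energies),
        "range_g_cm2": [csda_range(ion, material, e) for e in energies],
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
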