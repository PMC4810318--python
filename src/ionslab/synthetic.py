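"""Synthetic inputs: GCR-like flux spectra, cross-section datasets, and
Bragg-curve fixtures.

None of the study inputs require downloads: the galactic-cosmic-ray-like
spectrum is a parametric stand-in for the operational flux models used in
mission analysis (a power law in total energy with a solar-modulation-
controlled low-energy roll-off), the cross-section generator draws noisy
measurements from the geometric model, and the Bragg fixture builds a
rise-peak-tail curve with known ground truth for exercising the peak
analysis.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import CONSTANTS
from .cross_sections import CrossSectionRecord, GeometricParams, sigma_cc
from .transport import BraggCurve

#: Default species abundances (fraction of total particle flux).
#: Hydrogen and helium carry ~99% of the flux; the 1% of heavies is split
#: among the dosimetrically dominant even-Z species, with the iron share
#: set so that the unshielded average quality factor of the default field
#: lands in the free-space 6-7 band (see docs/methods.md).
DEFAULT_ABUNDANCES: dict[tuple[int, int], float] = {
    (1, 1): 0.87,
    (2, 4): 0.12,
    (6, 12): 0.00375,
    (8, 16): 0.00345,
    (12, 24): 0.0011,
    (14, 28): 0.0011,
    (26, 56): 0.0006,
}


@dataclass(frozen=True)
class SpectrumShapeParams:
    """Shape of the synthetic GCR spectrum.

    Differential flux per species:

        phi(T) ∝ (T + m)^(-spectral_index) * (T / (T + E0))^rolloff_exponent

    with T the kinetic energy per nucleon, m the nucleon rest energy and
    E0 = ``modulation`` the MV-like roll-off scale: larger modulation
    suppresses the low-energy flux (solar maximum), leaving the high-energy
    power law untouched.  ``spectral_index`` defaults to the conventional
    2.7 high-energy GCR slope; the default modulation of 600 corresponds to
    a weak solar maximum.
    """

    spectral_index: float = 2.7
    modulation: float = 600.0
    rolloff_exponent: float = 2.0
    abundances: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_ABUNDANCES))
    e_min: float = 10.0
    e_max: float = 5.0e4
    n_grid: int = 256

    def __post_init__(self) -> None:
        if self.spectral_index <= 1:
            raise ValueError("spectral_index must be > 1")
        if self.modulation < 0 or self.rolloff_exponent < 0:
            raise ValueError("modulation and rolloff_exponent must be >= 0")
        total = sum(self.abundances.values())
        if total <= 0 or not np.isfinite(total):
            raise ValueError("abundances must be positive and finite")


@dataclass
class FluxSpectrum:
    """Per-species energy grids and differential fluence.

    ``flux[(z, a)]`` is d(phi)/dT in (cm^2 MeV/nuc)^-1 on ``energy[(z, a)]``
    (MeV/nuc), normalized so the integral over energy equals the species
    abundance (total flux of 1 particle per cm^2).
    """

    energy: dict[tuple[int, int], np.ndarray]
    flux: dict[tuple[int, int], np.ndarray]
    modulation_parameter: float

    def species_fractions(self) -> dict[tuple[int, int], float]:
        integ = {k: float(np.trapezoid(self.flux[k], self.energy[k]))
                 for k in self.flux}
        total = sum(integ.values())
        return {k: v / total for k, v in integ.items()}

    def heavy_fraction(self) -> float:
        """Fraction of total flux carried by ions with Z > 2."""
        fr = self.species_fractions()
        return sum(v for (z, _a), v in fr.items() if z > 2)

    def fraction_below(self, e_cut: float) -> float:
        """Fraction of the total flux below an energy cut (MeV/nuc)."""
        num = tot = 0.0
        for k, e in self.energy.items():
            f = self.flux[k]
            tot += np.trapezoid(f, e)
            m = e <= e_cut
            if m.sum() > 1:
                num += np.trapezoid(f[m], e[m])
        return num / tot

    def sample(self, n: int, rng: np.random.Generator | int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Draw n particles: arrays (z, a, energy_per_nucleon)."""
        z, a, e, _w = self.sample_weighted(n, rng, stratified=False)
        return z, a, e

    def sample_weighted(self, n: int, rng: np.random.Generator | int,
                        stratified: bool = True
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                   np.ndarray]:
        """Draw n particles with statistical weights.

        With ``stratified=True`` the species allocation is a 50/50 blend of
        abundance-proportional and equal-per-species, and each particle
        carries the weight that makes every weighted estimator unbiased.
        This is plain importance sampling over species: heavy ions are only
        ~1% of the flux but dominate the dose equivalent, so proportional
        sampling leaves <Q> at the mercy of a few dozen iron draws.
        """
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        keys = list(self.flux)
        fracs = self.species_fractions()
        f = np.array([fracs[k] for k in keys])
        f = f / f.sum()
        if stratified:
            q = 0.5 * f + 0.5 / len(keys)
            counts = np.floor(n * q).astype(int)
            counts[np.argmax(counts)] += n - counts.sum()
        else:
            counts = rng.multinomial(n, f)
        z = np.empty(n, dtype=int)
        a = np.empty(n, dtype=int)
        energy = np.empty(n, dtype=float)
        weight = np.empty(n, dtype=float)
        pos = 0
        for i, key in enumerate(keys):
            c = int(counts[i])
            if c == 0:
                continue
            sl = slice(pos, pos + c)
            pos += c
            e_grid, fl = self.energy[key], self.flux[key]
            cdf = np.concatenate(([0.0], np.cumsum(
                0.5 * (fl[1:] + fl[:-1]) * np.diff(e_grid))))
            cdf /= cdf[-1]
            energy[sl] = np.interp(rng.random(c), cdf, e_grid)
            z[sl], a[sl] = key
            weight[sl] = f[i] * n / c if stratified else 1.0
        perm = rng.permutation(n)
        return z[perm], a[perm], energy[perm], weight[perm]

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for (z, a), e in self.energy.items():
            f = self.flux[(z, a)]
            rows.append(pd.DataFrame({"z": z, "a": a,
                                      "energy_mev_per_nuc": e,
                                      "flux_per_cm2_mev": f}))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                                  float_format="%.6g")


def make_gcr_spectrum(params: SpectrumShapeParams = SpectrumShapeParams(),
                      seed: int = 0) -> FluxSpectrum:
    """Build the parametric GCR-like spectrum.

    Deterministic given ``params`` (the seed is accepted for interface
    uniformity with the other generators).  Increasing the modulation
    parameter strictly decreases the flux fraction below a few hundred
    MeV/nuc while leaving the 10 GeV/nuc tail essentially unchanged.
    """
    total = sum(params.abundances.values())
    energy: dict[tuple[int, int], np.ndarray] = {}
    flux: dict[tuple[int, int], np.ndarray] = {}
    m = CONSTANTS.nucleon_rest_energy
    for key, ab in params.abundances.items():
        e = np.geomspace(params.e_min, params.e_max, params.n_grid)
        shape = ((e + m) ** (-params.spectral_index)
                 * (e / (e + params.modulation)) ** params.rolloff_exponent)
        norm = np.trapezoid(shape, e)
        energy[key] = e
        flux[key] = shape * (ab / total) / norm
    return FluxSpectrum(energy=energy, flux=flux,
                        modulation_parameter=params.modulation)


# --------------------------------------------------------------------------
# Cross-section datasets
# --------------------------------------------------------------------------

#: Projectile/target pairs spanning the systems for which charge-changing
#: data exist: light-to-heavy projectiles on light-to-heavy targets.
DEFAULT_XSEC_PAIRS: list[tuple[int, int, str, int]] = [
    (z, a, sym, at)
    for (z, a) in [(2, 4), (5, 10), (6, 12), (8, 16), (12, 24), (26, 56)]
    for (sym, at) in [("H", 1), ("C", 12), ("Al", 27),
                      ("Cu", 64), ("Sn", 119)]
]


def make_xsec_dataset(truth: GeometricParams = GeometricParams(),
                      pairs: Sequence[tuple[int, int, str, int]] | None = None,
                      noise_fraction: float = 0.10,
                      seed: int = 0,
                      energy: float = 600.0) -> list[CrossSectionRecord]:
    """Noisy cross-section measurements drawn from the geometric model.

    sigma_i = model(truth) * (1 + noise_fraction * N(0,1)), with quoted
    errors equal to noise_fraction * sigma_model.  noise_fraction = 0 puts
    the records exactly on the model surface.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    if pairs is None:
        pairs = DEFAULT_XSEC_PAIRS
    rng = np.random.default_rng(seed)
    records = []
    for z_p, a_p, sym, a_t in pairs:
        model = sigma_cc(a_p, a_t, truth)
        noisy = model * max(1.0 + noise_fraction * rng.standard_normal(),
                            0.05)
        records.append(CrossSectionRecord(
            z_proj=z_p, a_proj=a_p, target_symbol=sym, a_targ=float(a_t),
            energy=energy, sigma_cc=float(noisy),
            sigma_err=float(noise_fraction * model)))
    return records


# --------------------------------------------------------------------------
# Bragg-curve fixtures
# --------------------------------------------------------------------------

def make_bragg_fixture(peak_depth: float = 8.13, peak_ratio: float = 6.5,
                       noise_fraction: float = 0.0, seed: int = 0,
                       step: float = 0.05, tail_length: float = 5.0
                       ) -> tuple[BraggCurve, dict[str, float]]:
    """Analytic rise-peak-tail curve with known ground truth.

    The curve is a Gaussian peak (width peak_depth/30, the scale set by
    range straggling and beamline momentum spread in measured curves) on a
    unit entrance plateau, with a smooth fragment-like distal tail whose
    slope vanishes at the peak so the apex location is not biased.  The
    grid curve is optionally perturbed by multiplicative Gaussian noise
    (the entrance plane is re-normalized to exactly 1).  Returns the curve
    and a dict with the truth actually placed on the grid.
    """
    if peak_depth <= 0:
        raise ValueError("peak_depth must be > 0")
    grid = np.arange(0.0, peak_depth + tail_length + 0.5 * step, step)
    p_grid = grid[np.argmin(np.abs(grid - peak_depth))]
    w = p_grid / 30.0
    ratio = 1.0 + (peak_ratio - 1.0) * np.exp(
        -0.5 * ((grid - p_grid) / w) ** 2)
    post = grid > p_grid
    x = (grid[post] - p_grid) / 2.0
    ratio[post] += 0.025 * peak_ratio * x * x * np.exp(-x)
    rng = np.random.default_rng(seed)
    if noise_fraction > 0:
        ratio *= 1.0 + noise_fraction * rng.standard_normal(grid.size)
        ratio /= ratio[0]
    comp = pd.DataFrame({6: np.ones_like(grid)}, index=grid)
    curve = BraggCurve(depth_grid=grid, ionization_ratio=ratio,
                       composition=comp, n_primaries=0)
    truth = {"peak_depth": float(p_grid),
             "peak_ratio": float(peak_ratio), "step": float(step)}
    return curve, truth
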