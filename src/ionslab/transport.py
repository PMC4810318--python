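"""1-D Monte Carlo slab transport: continuous slowing plus stochastic
charge-changing interactions.

Each primary is followed through the slab in depth (areal density,
g cm^-2).  Between nuclear interactions the ion slows deterministically
along its CSDA range-energy curve; the distance to the next
charge-changing interaction is sampled from the exponential free-path
distribution (a per-step Bernoulli alternative is available).  At an
interaction the projectile is replaced by the products of a branching-table
draw (heaviest fragment plus conservation protons; neutrons are counted
but not transported), each inheriting the projectile's velocity perturbed
by Goldhaber momentum kicks.  Fragments are transported recursively.

Ionization scoring mimics a parallel-plate chamber pair: at every depth
plane of a regular grid the stopping powers of all charged particles
crossing the plane are summed and normalized to the entrance plane, giving
the familiar before/after ionization ratio of a measured Bragg curve.
Particles carried further than ``scoring_radius_mm`` from the beam axis by
their accumulated transverse deflections are excluded from scoring,
mirroring the finite lateral acceptance of a real scoring volume.

Two small stochastic refinements matter only near the stopping point and
are configurable: Gaussian range straggling (Bohr-like, sigma_R = 1.2% of
range / sqrt(A)) and an optional Gaussian spread of the beam energy.
Without straggling, every primary of a monoenergetic beam stops at exactly
the CSDA range and the single-particle LET divergence prints through to
the binned curve; with it, the peak amplitude and width take the values
familiar from measured curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import CONSTANTS
from .cross_sections import GeometricProvider, mean_free_path
from .fragmentation import (BranchingTable, GoldhaberParams,
                            default_branching_table, sample_fragments)
from .materials import Material
from .physics import (ENERGY_FLOOR, IonState, let_water, range_table,
                      stopping_power)

#: Relative range-straggling width for a proton (Bohr-like); scales 1/sqrt(A).
PROTON_RANGE_STRAGGLING = 0.012


@dataclass
class TransportConfig:
    """Knobs of the Monte Carlo transport.

    step : depth grid spacing for scoring and Bernoulli stepping, g cm^-2.
    rng_seed : seed for the whole simulation (one generator drives
        free paths, branching draws and Goldhaber kicks).
    fragmentation_enabled : switch nuclear interactions off to recover
        pure deterministic slowing.
    scoring_radius_mm : lateral acceptance of the scoring planes.
    n_primaries : number of incident ions.
    straggling : Gaussian range straggling on/off.
    energy_spread_fraction : relative sigma of the incident beam energy
        (0 = monoenergetic).
    interaction_sampling : "exponential" free-path sampling (default) or
        per-step "bernoulli" with p = step / lambda.
    """

    step: float = 0.05
    rng_seed: int = 12345
    fragmentation_enabled: bool = True
    scoring_radius_mm: float = 100.0
    n_primaries: int = 1000
    straggling: bool = True
    energy_spread_fraction: float = 0.0
    interaction_sampling: str = "exponential"

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.n_primaries < 1:
            raise ValueError("n_primaries must be >= 1")
        if self.interaction_sampling not in ("exponential", "bernoulli"):
            raise ValueError("interaction_sampling must be 'exponential' "
                             "or 'bernoulli'")


@dataclass
class ParticleRecord:
    """One transported particle (a primary or a fragment)."""

    particle_id: int
    parent_id: int          # -1 for primaries
    ion: IonState           # state at creation
    depth: float            # creation depth, g cm^-2
    weight: float = 1.0
    transverse_offset: float = 0.0   # mm, at creation
    tan_deflection: float = 0.0      # offset growth per linear cm of path
    generation: int = 0
    alive: bool = True
    # filled during transport:
    stop_depth: float = np.inf       # where the ion would range out
    end_depth: float = np.inf        # where this segment actually ends
    fate: str = "in_flight"          # fragmented | stopped | exited
    exit_energy: float = 0.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass
class TransportResult:
    """Depth-resolved history of a slab simulation."""

    records: list[ParticleRecord]
    material: Material
    max_depth: float
    config: TransportConfig
    n_neutrons: int = 0
    #: per interaction: (primary LET, summed fragment LET), keV/um in water
    let_budget: list[tuple[float, float]] = field(default_factory=list)

    @property
    def primaries(self) -> list[ParticleRecord]:
        return [r for r in self.records if r.parent_id == -1]

    @property
    def exits(self) -> list[ParticleRecord]:
        return [r for r in self.records if r.fate == "exited"]

    def primary_survival(self, depths) -> np.ndarray:
        """Fraction of primaries still intact (not fragmented, not stopped)
        at each depth."""
        ends = np.array([r.end_depth for r in self.primaries])
        depths = np.atleast_1d(np.asarray(depths, dtype=float))
        return np.array([(ends > x).mean() for x in depths])

    def charge_changing_survival(self, depths) -> np.ndarray:
        """Fraction of primaries that have not undergone a charge-changing
        interaction by each depth (an ion that ranges out intact still
        counts as surviving in this sense, matching the e^(-x/lambda) law).
        """
        prim = self.primaries
        ends = np.array([r.end_depth for r in prim])
        fragged = np.array([r.fate == "fragmented" for r in prim])
        depths = np.atleast_1d(np.asarray(depths, dtype=float))
        return np.array([1.0 - (fragged & (ends <= x)).mean()
                         for x in depths])


def _mfp_for(z: int, a: int, energy: float, material: Material,
             sigma_provider) -> float:
    return mean_free_path(IonState(z, a, max(energy, ENERGY_FLOOR)),
                          material, sigma_provider)


def transport_slab(beam: IonState, material: Material, max_depth: float,
                   config: TransportConfig,
                   sigma_provider=None,
                   branching: BranchingTable | None = None,
                   goldhaber: GoldhaberParams = GoldhaberParams()
                   ) -> TransportResult:
    """Transport ``config.n_primaries`` beam ions through a slab.

    Returns the full particle history; fragments are transported
    recursively until they stop, exit, or fragment in turn.
    """
    if beam.energy_per_nucleon < ENERGY_FLOOR:
        raise ValueError("beam energy below the validity floor")
    if max_depth <= 0:
        raise ValueError("max_depth must be > 0")
    if sigma_provider is None:
        sigma_provider = GeometricProvider()
    if branching is None:
        branching = default_branching_table()
    rng = np.random.default_rng(config.rng_seed)

    mfp_cache: dict[tuple[int, int], float] = {}

    def get_mfp(z: int, a: int, energy: float) -> float | None:
        """Charge-changing mfp, or None when the species cannot fragment."""
        if not config.fragmentation_enabled or z < 2:
            return None
        if not branching.covers(z):
            return None
        key = (z, a)
        if key not in mfp_cache:
            mfp_cache[key] = _mfp_for(z, a, energy, material, sigma_provider)
            if config.interaction_sampling == "bernoulli" and \
                    config.step > mfp_cache[key] / 10.0:
                warnings.warn(
                    f"step {config.step} exceeds lambda/10 for Z={z}; "
                    "first-order interaction probability is inaccurate",
                    stacklevel=2)
        return mfp_cache[key]

    records: list[ParticleRecord] = []
    let_budget: list[tuple[float, float]] = []
    n_neutrons = 0
    next_id = 0

    stack: list[ParticleRecord] = []
    for _ in range(config.n_primaries):
        e0 = beam.energy_per_nucleon
        if config.energy_spread_fraction > 0:
            e0 = max(ENERGY_FLOOR,
                     rng.normal(e0, config.energy_spread_fraction * e0))
        stack.append(ParticleRecord(particle_id=next_id, parent_id=-1,
                                    ion=beam.with_energy(e0), depth=0.0))
        next_id += 1

    while stack:
        rec = stack.pop()
        ion = rec.ion
        z, a = ion.z_proj, ion.a_proj
        if ion.energy_per_nucleon < ENERGY_FLOOR:
            rec.stop_depth = rec.end_depth = rec.depth
            rec.fate = "stopped"
            rec.alive = False
            records.append(rec)
            continue
        table = range_table(ion, material)
        residual = table.range_of(ion.energy_per_nucleon)
        if config.straggling:
            residual += rng.normal(
                0.0, PROTON_RANGE_STRAGGLING * residual / np.sqrt(a))
            residual = max(residual, 0.0)
        rec.stop_depth = rec.depth + residual

        lam = get_mfp(z, a, ion.energy_per_nucleon)
        if lam is None:
            interaction_depth = np.inf
        elif config.interaction_sampling == "exponential":
            interaction_depth = rec.depth + rng.exponential(lam)
        else:
            p = min(config.step / lam, 1.0)
            interaction_depth = rec.depth + rng.geometric(p) * config.step

        rec.end_depth = min(rec.stop_depth, interaction_depth, max_depth)
        if rec.end_depth == interaction_depth:
            rec.fate = "fragmented"
            rec.alive = False
            # energy per nucleon at the interaction point (residual range
            # measured from the, possibly straggled, stopping depth)
            e_here = table.energy_of(max(rec.stop_depth - rec.end_depth,
                                         0.0))
            e_here = max(float(e_here), ENERGY_FLOOR)
            event = sample_fragments(ion.with_energy(e_here), branching,
                                     rng, goldhaber)
            n_neutrons += event.n_neutrons
            # LET budget at the vertex: all products emerge at (essentially)
            # the primary's velocity, so the comparison is at equal beta.
            let_p = let_water(ion, e_here)
            let_f = 0.0
            for frag, ang in zip(event.fragments,
                                 event.transverse_angles_deg):
                let_f += let_water(frag.with_energy(e_here))
                child = ParticleRecord(
                    particle_id=next_id, parent_id=rec.particle_id,
                    ion=frag, depth=rec.end_depth, weight=rec.weight,
                    transverse_offset=rec.transverse_offset
                    + rec.tan_deflection
                    * (rec.end_depth - rec.depth) / material.density * 10.0,
                    tan_deflection=rec.tan_deflection
                    + float(np.tan(np.radians(ang))),
                    generation=rec.generation + 1)
                next_id += 1
                stack.append(child)
            let_budget.append((let_p, let_f))
        elif rec.end_depth == rec.stop_depth:
            rec.fate = "stopped"
            rec.alive = False
        else:
            rec.fate = "exited"
            rec.exit_energy = float(table.energy_of(
                rec.stop_depth - max_depth))
        records.append(rec)

    return TransportResult(records=records, material=material,
                           max_depth=max_depth, config=config,
                           n_neutrons=n_neutrons, let_budget=let_budget)


# --------------------------------------------------------------------------
# Bragg-curve scoring
# --------------------------------------------------------------------------

@dataclass
class BraggCurve:
    """Depth grid, ionization ratio, and per-charge fluence composition."""

    depth_grid: np.ndarray
    ionization_ratio: np.ndarray
    composition: pd.DataFrame      # index: depth, columns: charge Z
    n_primaries: int

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"depth_g_cm2": self.depth_grid,
                           "ionization_ratio": self.ionization_ratio})
        for col in self.composition.columns:
            df[f"frac_Z{col}"] = self.composition[col].to_numpy()
        df.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BraggCurve":
        df = pd.read_csv(path)
        zcols = [c for c in df.columns if c.startswith("frac_Z")]
        comp = pd.DataFrame(
            {int(c[6:]): df[c].to_numpy() for c in zcols},
            index=df["depth_g_cm2"].to_numpy())
        return cls(depth_grid=df["depth_g_cm2"].to_numpy(),
                   ionization_ratio=df["ionization_ratio"].to_numpy(),
                   composition=comp, n_primaries=0)


def _mass_stopping(z: int, material: Material, energies: np.ndarray
                   ) -> np.ndarray:
    """Vectorized Bethe mass stopping power for charge z (MeV cm^2/g)."""
    g = 1.0 + energies / CONSTANTS.nucleon_rest_energy
    beta2 = 1.0 - 1.0 / (g * g)
    arg = (2.0 * CONSTANTS.electron_rest_energy * 1e6 * beta2 / (1.0 - beta2)
           / material.mean_excitation_energy)
    return (CONSTANTS.k * material.z_over_a * z * z / beta2
            * (np.log(arg) - beta2))


def score_bragg(result: TransportResult) -> BraggCurve:
    """Bin the particle history into an ionization-ratio Bragg curve."""
    cfg = result.config
    material = result.material
    grid = np.arange(0.0, result.max_depth + 0.5 * cfg.step, cfg.step)
    ionization = np.zeros_like(grid)
    comp: dict[int, np.ndarray] = {}

    for rec in result.records:
        ion = rec.ion
        if ion.energy_per_nucleon < ENERGY_FLOOR:
            continue
        table = range_table(ion, material)
        r_floor = table.range_of(ENERGY_FLOOR) * 1.0000001
        # planes this particle crosses with energy above the floor
        lo = rec.depth
        hi = min(rec.end_depth, rec.stop_depth - r_floor)
        if hi <= lo:
            continue
        k0 = int(np.ceil(lo / cfg.step - 1e-9))
        k1 = int(np.floor(hi / cfg.step + 1e-9))
        if k1 < k0:
            continue
        k = np.arange(k0, min(k1, grid.size - 1) + 1)
        x = grid[k]
        # lateral acceptance cut
        if rec.tan_deflection != 0.0 or rec.transverse_offset != 0.0:
            off = rec.transverse_offset + rec.tan_deflection \
                * (x - rec.depth) / material.density * 10.0
            inside = np.abs(off) <= cfg.scoring_radius_mm
            if not inside.any():
                continue
            k, x = k[inside], x[inside]
        e = table.energy_of(rec.stop_depth - x)
        e = np.maximum(e, ENERGY_FLOOR)
        ionization[k] += rec.weight * _mass_stopping(ion.z_proj, material, e)
        arr = comp.setdefault(ion.z_proj, np.zeros_like(grid))
        np.add.at(arr, k, rec.weight)

    entrance = ionization[0]
    if entrance <= 0:
        raise ValueError("no particles crossed the entrance plane")
    total = sum(comp.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = {z: np.where(total > 0, arr / np.maximum(total, 1e-300), 0.0)
                for z, arr in comp.items()}
    composition = pd.DataFrame(frac, index=grid).sort_index(axis=1)
    return BraggCurve(depth_grid=grid, ionization_ratio=ionization / entrance,
                      composition=composition,
                      n_primaries=cfg.n_primaries)


def bragg_curve(beam: IonState, material: Material, max_depth: float,
                config: TransportConfig, sigma_provider=None,
                branching: BranchingTable | None = None) -> BraggCurve:
    """Simulate and score a Bragg curve in one call."""
    result = transport_slab(beam, material, max_depth, config,
                            sigma_provider, branching)
    return score_bragg(result)


# --------------------------------------------------------------------------
# Curve analysis
# --------------------------------------------------------------------------

@dataclass
class PeakSummary:
    peak_depth: float
    peak_ratio: float
    distal_integral: float
    rise_slope: float
    no_peak: bool = False      # flagged when the curve is monotone decreasing


def peak_analysis(curve: BraggCurve) -> PeakSummary:
    """Locate and characterize the Bragg peak of a scored curve.

    Peak = argmax of the ionization ratio (smallest depth on ties); the
    distal integral is the ratio summed beyond the peak times the grid
    spacing; the rise slope is the mean gradient from entrance to peak.
    """
    ratio = np.asarray(curve.ionization_ratio, dtype=float)
    if ratio.size == 0 or np.all(ratio == 0):
        raise ValueError("empty or all-zero curve")
    idx = int(np.argmax(ratio))
    depth = float(curve.depth_grid[idx])
    step = float(np.median(np.diff(curve.depth_grid))) \
        if curve.depth_grid.size > 1 else 0.0
    distal = float(np.sum(ratio[idx + 1:]) * step)
    slope = (ratio[idx] - ratio[0]) / depth if depth > 0 else 0.0
    return PeakSummary(peak_depth=depth, peak_ratio=float(ratio[idx]),
                       distal_integral=distal, rise_slope=float(slope),
                       no_peak=(idx == 0))


def composition_at_depth(curve: BraggCurve, depth: float) -> dict[int, float]:
    """Fluence fraction per charge at the grid plane nearest ``depth``."""
    grid = curve.depth_grid
    if depth < grid[0] or depth > grid[-1]:
        raise ValueError(f"depth {depth} outside the simulated grid")
    idx = int(np.argmin(np.abs(grid - depth)))
    row = curve.composition.iloc[idx]
    total = float(row.sum())
    if total <= 0:
        raise ValueError(f"no particles at depth {depth}")
    return {int(z): float(v) / total for z, v in row.items() if v > 0}
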