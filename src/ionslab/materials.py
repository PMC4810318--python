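"""Target-medium definitions: elemental composition, density, I-value.

A :class:`Material` is a stoichiometric formula (list of elements with atom
counts), a bulk density and a mean excitation energy.  Built-in media cover
the three targets that matter for slab-transport studies of therapy beams
and spacecraft hulls: water, high-density polyethylene (CH2) and aluminum.
Mean excitation energies are the ICRU-recommended values.

Materials can also be loaded from a YAML registry, e.g.::

    lucite:
      density: 1.19
      mean_excitation_energy: 74.0
      components:
        - {z: 6, a: 12.011, stoichiometry: 5}
        - {z: 1, a: 1.008, stoichiometry: 8}
        - {z: 8, a: 15.999, stoichiometry: 2}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml


@dataclass(frozen=True)
class ElementComponent:
    """One element of a compound: atomic number, molar mass, atom count."""

    z_elem: int
    a_elem: float
    stoichiometry: float = 1.0

    def __post_init__(self) -> None:
        if self.z_elem < 1:
            raise ValueError("z_elem must be >= 1")
        if self.a_elem < self.z_elem:
            raise ValueError("a_elem must be >= z_elem")
        if self.stoichiometry <= 0:
            raise ValueError("stoichiometry must be > 0")


@dataclass(frozen=True)
class Material:
    """A homogeneous medium traversed by the beam.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"water"``.
    components : tuple of ElementComponent
        Stoichiometric formula.
    density : float
        Bulk density in g cm^-3.
    mean_excitation_energy : float
        I-value in eV entering the Bethe logarithm.
    """

    name: str
    components: tuple[ElementComponent, ...]
    density: float
    mean_excitation_energy: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.mean_excitation_energy <= 0:
            raise ValueError("mean_excitation_energy must be > 0")
        if not self.components:
            raise ValueError("material needs at least one component")
        if self.formula_mass <= 0:
            raise ValueError("formula mass must be > 0")

    @property
    def formula_mass(self) -> float:
        """Molar mass of one formula unit, g mol^-1."""
        return sum(c.a_elem * c.stoichiometry for c in self.components)

    @property
    def mass_fractions(self) -> tuple[float, ...]:
        m = self.formula_mass
        return tuple(c.a_elem * c.stoichiometry / m for c in self.components)

    @property
    def z_over_a(self) -> float:
        """Electrons per unit mass, <Z/A> in mol g^-1 (mass-fraction weighted)."""
        return sum(w * c.z_elem / c.a_elem
                   for w, c in zip(self.mass_fractions, self.components))


def _mk(name: str, comps: Iterable[tuple[int, float, float]],
        rho: float, i_ev: float) -> Material:
    return Material(name=name,
                    components=tuple(ElementComponent(z, a, n)
                                     for z, a, n in comps),
                    density=rho, mean_excitation_energy=i_ev)


# Built-ins use integer mass numbers; a_elem doubles as the g/mol
# approximation in the compound mean-free-path rule and as the nucleon
# count in the geometric cross-section formula.
WATER = _mk("water", [(1, 1.0, 2), (8, 16.0, 1)], 1.00, 75.0)
POLYETHYLENE = _mk("polyethylene", [(6, 12.0, 1), (1, 1.0, 2)], 0.97, 57.4)
ALUMINUM = _mk("aluminum", [(13, 27.0, 1)], 2.70, 166.0)

BUILTIN_MATERIALS: dict[str, Material] = {
    m.name: m for m in (WATER, POLYETHYLENE, ALUMINUM)
}


def get_material(name: str,
                 registry: dict[str, Material] | None = None) -> Material:
    """Look up a material by name in a registry (built-ins by default)."""
    table = dict(BUILTIN_MATERIALS)
    if registry:
        table.update(registry)
    try:
        return table[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; known: {sorted(table)}") from None


def load_materials_yaml(path: str | Path) -> dict[str, Material]:
    """Read a YAML materials registry (see module docstring for schema)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("materials YAML must map name -> definition")
    out: dict[str, Material] = {}
    for name, spec in raw.items():
        comps = [(int(c["z"]), float(c["a"]), float(c.get("stoichiometry", 1)))
                 for c in spec["components"]]
        out[str(name).lower()] = _mk(str(name).lower(), comps,
                                     float(spec["density"]),
                                     float(spec["mean_excitation_energy"]))
    return out
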