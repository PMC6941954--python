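"""Topology of the carboxyl--water--carboxyl excess-proton model system.

The model system is a pair of deprotonated carboxyl groups with one water
molecule and one excess proton in between (net charge +1 e): ten atoms in
total.  Atom *roles* are fixed labels used throughout the package:

================  =========================================
role              meaning
================  =========================================
C1, C2            carboxyl carbons
O1a, O1b          oxygens of carboxyl group 1
O2a, O2b          oxygens of carboxyl group 2
Ow                water oxygen
H1, H2, H3        hydrogens; H2 is the transferable proton
================  =========================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ModelTopology", "make_default_topology"]

# standard atomic masses, amu
_MASSES = {"C": 12.011, "O": 15.999, "H": 1.008}


@dataclass(frozen=True)
class ModelTopology:
    """Atom roles, elements, masses and hydrogen ownership of the 10-atom system.

    Parameters
    ----------
    roles : tuple of str
        Unique atom labels; order defines the atom index used in Cartesian
        frames.
    elements : tuple of str
        Chemical element per atom, parallel to ``roles``.
    masses : tuple of float
        Atomic masses in amu, parallel to ``roles``.
    hydrogen_owners : dict
        Initial owner oxygen role for every hydrogen role.
    net_charge : int
        Net charge of the system (+1: one excess proton).
    """

    roles: tuple[str, ...]
    elements: tuple[str, ...]
    masses: tuple[float, ...]
    hydrogen_owners: dict[str, str] = field(default_factory=dict)
    net_charge: int = 1

    def __post_init__(self) -> None:
        if len(set(self.roles)) != len(self.roles):
            raise ValueError("atom roles must be unique")
        if not (len(self.roles) == len(self.elements) == len(self.masses)):
            raise ValueError("roles, elements and masses must be parallel")
        n_h = sum(e == "H" for e in self.elements)
        n_o = sum(e == "O" for e in self.elements)
        if n_h != 3 or n_o != 5:
            raise ValueError(
                f"model system requires 3 hydrogens and 5 oxygens, got {n_h} H / {n_o} O"
            )
        for h in self.hydrogens:
            if h not in self.hydrogen_owners:
                raise ValueError(f"hydrogen {h} has no initial owner oxygen")
            if self.hydrogen_owners[h] not in self.oxygens:
                raise ValueError(f"owner of {h} is not an oxygen")

    # -- role views ---------------------------------------------------------
    @property
    def hydrogens(self) -> tuple[str, ...]:
        return tuple(r for r, e in zip(self.roles, self.elements) if e == "H")

    @property
    def oxygens(self) -> tuple[str, ...]:
        return tuple(r for r, e in zip(self.roles, self.elements) if e == "O")

    @property
    def carboxyl_oxygens(self) -> tuple[str, ...]:
        return tuple(r for r in self.oxygens if r != self.water_oxygen)

    @property
    def water_oxygen(self) -> str:
        return "Ow"

    def index(self, role: str) -> int:
        """Atom index of *role* in Cartesian frames."""
        try:
            return self.roles.index(role)
        except ValueError:
            raise KeyError(f"no atom with role {role!r}") from None


def make_default_topology() -> ModelTopology:
    """Default 10-atom topology.

    H2 (the excess/transferable proton) and H3 start owned by the water
    oxygen; H1 sits on carboxyl oxygen O1a, so the water carries two
    hydrogens plus the shared excess proton between Ow and O1a.
    """
    roles = ("C1", "O1a", "O1b", "H1", "Ow", "H2", "H3", "C2", "O2a", "O2b")
    elements = ("C", "O", "O", "H", "O", "H", "H", "C", "O", "O")
    masses = tuple(_MASSES[e] for e in elements)
    owners = {"H1": "O1a", "H2": "Ow", "H3": "Ow"}
    return ModelTopology(roles=roles, elements=elements, masses=masses,
                         hydrogen_owners=owners, net_charge=1)
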