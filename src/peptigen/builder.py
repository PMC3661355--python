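"""Residue-by-residue construction of all-heavy-atom peptide models.

A chain grows at the C terminus.  Appending residue ``i`` consumes four
internal coordinates at the junction — the preceding residue's psi
(``psi_im1``), the peptide-bond torsion ``omega``, the new residue's
``phi`` and the ``peptide_bond`` length — plus the new residue's own
bond lengths and planar angles:

* N_i   from (N_{i-1}, CA_{i-1}, C_{i-1})  via peptide_bond, CA_C_N_angle, psi_im1
* CA_i  from (CA_{i-1}, C_{i-1}, N_i)      via CA_N_length, C_N_CA_angle, omega
* C_i   from (C_{i-1}, N_i, CA_i)          via CA_C_length, N_CA_C_angle, phi
* O_i   from (N_i, CA_i, C_i)              via C_O_length, CA_C_O_angle, N_CA_C_O_diangle

followed by the side-chain atoms of the residue's topology table.  Only
heavy atoms are placed; hydrogens are never added.  Note that psi of the
last residue is undefined until another residue is appended — no API
reports it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geom
from .geometry import Geo, geometry, sidechain_topology

__all__ = [
    "Atom",
    "Residue",
    "Peptide",
    "initialize_res",
    "initialize_residue",
    "add_residue",
    "make_structure",
    "make_extended_structure",
    "make_structure_from_geos",
]


@dataclass
class Atom:
    """One named heavy atom with a Cartesian position in Angstroms."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be nonempty")
        self.position = np.asarray(self.position, dtype=float)
        if not self.name.startswith(self.element):
            raise ValueError(
                f"element {self.element!r} inconsistent with atom name {self.name!r}"
            )


@dataclass
class Residue:
    """One residue: 3-letter name, 1-based index, and its atoms in placement order."""

    name3: str
    index: int
    atoms: dict[str, Atom] = field(default_factory=dict)

    def __getitem__(self, atom_name: str) -> np.ndarray:
        return self.atoms[atom_name].position

    def __contains__(self, atom_name: str) -> bool:
        return atom_name in self.atoms

    def add_atom(self, name: str, position) -> None:
        if name in self.atoms:
            raise ValueError(f"duplicate atom {name} in residue {self.index}")
        self.atoms[name] = Atom(name, name[0], position)

    @property
    def has_complete_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C", "O"))


class Peptide:
    """An ordered single chain of residues, indices 1..n."""

    def __init__(self, chain_id: str = "A"):
        if len(chain_id) != 1:
            raise ValueError("chain_id must be a single character")
        self.chain_id = chain_id
        self.residues: list[Residue] = []

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> Residue:
        return self.residues[i]

    def __iter__(self):
        return iter(self.residues)

    def append(self, residue: Residue) -> None:
        expected = len(self.residues) + 1
        if residue.index != expected:
            raise ValueError(
                f"residue index {residue.index} breaks 1..n numbering "
                f"(expected {expected})"
            )
        self.residues.append(residue)

    @property
    def sequence(self) -> str:
        from .geometry import THREE_TO_ONE

        return "".join(THREE_TO_ONE.get(r.name3, "X") for r in self.residues)

    def atom_coords(self, atom_names=("N", "CA", "C"), n_residues: int | None = None):
        """Stacked coordinates of the named atoms over the first ``n_residues``."""
        n = len(self.residues) if n_residues is None else n_residues
        rows = []
        for res in self.residues[:n]:
            for name in atom_names:
                rows.append(res[name])
        return np.asarray(rows)

    def transformed(self, rotation, translation) -> "Peptide":
        """A rigidly moved copy: ``x -> rotation @ x + translation``."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = Peptide(self.chain_id)
        for res in self.residues:
            new = Residue(res.name3, res.index)
            for atom in res.atoms.values():
                new.add_atom(atom.name, rotation @ atom.position + translation)
            out.append(new)
        return out

    def __repr__(self):
        return f"<Peptide chain {self.chain_id}, {len(self)} residues>"


def _place_sidechain(res: Residue, geo: Geo) -> None:
    for atom in sidechain_topology(geo.residue_code):
        a, b, c = (res[name] for name in atom.refs)
        pos = geom.place_atom(
            a,
            b,
            c,
            getattr(geo, atom.length_key),
            getattr(geo, atom.angle_key),
            getattr(geo, atom.diangle_key),
        )
        res.add_atom(atom.name, pos)


def initialize_res(geo_or_code: Geo | str, chain_id: str = "A") -> Peptide:
    """Create a new single-residue peptide in the canonical frame.

    The canonical frame puts N at the origin, CA on the +x axis at
    CA_N_length, and C in the z = 0 plane with y > 0 at N_CA_C_angle.
    Accepts a ``Geo`` or a single-letter code (default geometry).
    """
    geo = geometry(geo_or_code) if isinstance(geo_or_code, str) else geo_or_code
    res = Residue(geo.residue_name, 1)
    n = np.zeros(3)
    ca = np.array([geo.CA_N_length, 0.0, 0.0])
    theta = np.radians(geo.N_CA_C_angle)
    c = ca + geo.CA_C_length * np.array([-np.cos(theta), np.sin(theta), 0.0])
    res.add_atom("N", n)
    res.add_atom("CA", ca)
    res.add_atom("C", c)
    res.add_atom(
        "O",
        geom.place_atom(n, ca, c, geo.C_O_length, geo.CA_C_O_angle, geo.N_CA_C_O_diangle),
    )
    _place_sidechain(res, geo)
    pep = Peptide(chain_id)
    pep.append(res)
    return pep


# spec-facing alias
initialize_residue = initialize_res


def add_residue(
    pep: Peptide,
    geo_or_code: Geo | str,
    phi: float | None = None,
    psi_im1: float | None = None,
) -> Peptide:
    """Append one residue at the C terminus of ``pep`` (in place).

    Two call styles:

    * ``add_residue(pep, geo)`` — use the geometry object as-is.
    * ``add_residue(pep, "A", phi, psi_im1)`` — default geometry for the
      coded amino acid with the two backbone torsions overridden.
    """
    if len(pep) == 0:
        raise ValueError("cannot add a residue to an empty peptide")
    if isinstance(geo_or_code, str):
        if phi is None or psi_im1 is None:
            raise TypeError(
                "add_residue(pep, code, phi, psi_im1) requires both torsions"
            )
        geo = geometry(geo_or_code)
        geo.phi = float(phi)
        geo.psi_im1 = float(psi_im1)
    else:
        if phi is not None or psi_im1 is not None:
            raise TypeError("pass torsions via the Geo object or use the code overload")
        geo = geo_or_code

    prev = pep[len(pep) - 1]
    res = Residue(geo.residue_name, len(pep) + 1)
    n = geom.place_atom(
        prev["N"], prev["CA"], prev["C"], geo.peptide_bond, geo.CA_C_N_angle, geo.psi_im1
    )
    ca = geom.place_atom(
        prev["CA"], prev["C"], n, geo.CA_N_length, geo.C_N_CA_angle, geo.omega
    )
    c = geom.place_atom(prev["C"], n, ca, geo.CA_C_length, geo.N_CA_C_angle, geo.phi)
    res.add_atom("N", n)
    res.add_atom("CA", ca)
    res.add_atom("C", c)
    res.add_atom(
        "O",
        geom.place_atom(n, ca, c, geo.C_O_length, geo.CA_C_O_angle, geo.N_CA_C_O_diangle),
    )
    _place_sidechain(res, geo)
    pep.append(res)
    return pep


def make_structure(
    sequence: str,
    phi_list,
    psi_im1_list,
    omega_list=None,
) -> Peptide:
    """Build an entire peptide from a sequence and backbone angle lists.

    The angle lists have length ``n - 1``: element ``k`` parameterizes
    the junction that places residue ``k + 2`` (its phi, the preceding
    residue's psi, and optionally its omega).
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    phi_list = list(phi_list)
    psi_im1_list = list(psi_im1_list)
    if len(phi_list) != n - 1 or len(psi_im1_list) != n - 1:
        raise ValueError(
            f"angle lists must have length n-1 = {n - 1}, got "
            f"{len(phi_list)} phi and {len(psi_im1_list)} psi values"
        )
    if omega_list is not None:
        omega_list = list(omega_list)
        if len(omega_list) != n - 1:
            raise ValueError(f"omega list must have length n-1 = {n - 1}")

    pep = initialize_res(sequence[0])
    for k in range(n - 1):
        geo = geometry(sequence[k + 1])
        geo.phi = float(phi_list[k])
        geo.psi_im1 = float(psi_im1_list[k])
        if omega_list is not None:
            geo.omega = float(omega_list[k])
        add_residue(pep, geo)
    return pep


def make_extended_structure(sequence: str) -> Peptide:
    """Build a peptide in the extended conformation (phi=-120, psi=140)."""
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    pep = initialize_res(sequence[0])
    for code in sequence[1:]:
        add_residue(pep, geometry(code))
    return pep


def make_structure_from_geos(geos) -> Peptide:
    """Build a peptide from a list of geometry objects, first to last."""
    geos = list(geos)
    if not geos:
        raise ValueError("need at least one geometry object")
    pep = initialize_res(geos[0])
    for geo in geos[1:]:
        add_residue(pep, geo)
    return pep
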