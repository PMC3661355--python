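"""Backbone extraction, reconstruction at four fidelity levels, and RMSD scoring.

The evaluation loop: measure every backbone internal coordinate of a
reference chain, rebuild the chain applying only a chosen subset of the
measured values (remaining parameters stay at their ideal-geometry
defaults), superpose, and report the backbone RMSD.  The four fidelity
levels correspond to applying

* ``PHI_PSI``                — the phi and psi torsions only,
* ``PHI_PSI_OMEGA``          — phi, psi and the peptide-bond torsion omega,
* ``ALL_ANGLES``             — all torsions plus all planar bond angles,
* ``ALL_LENGTHS_AND_ANGLES`` — every measured length and angle.

RMSD is computed over the N, CA, C backbone trace after Kabsch
superposition on the scored prefix itself; the carbonyl O is excluded by
default so that the O-dihedral convention cannot confound the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from . import geom
from .builder import Peptide, make_structure_from_geos
from .geometry import _wrap_angle, geometry

__all__ = [
    "FidelityLevel",
    "BackboneParams",
    "extract_backbone_params",
    "reconstruct",
    "backbone_rmsd",
    "reconstruction_report",
    "FULL",
]

FULL = None  # sentinel: score the entire chain


class FidelityLevel(Enum):
    """Which measured backbone parameters a reconstruction applies."""

    PHI_PSI = "phi_psi"
    PHI_PSI_OMEGA = "phi_psi_omega"
    ALL_ANGLES = "all_angles"
    ALL_LENGTHS_AND_ANGLES = "all_lengths_and_angles"


@dataclass
class BackboneParams:
    """Backbone internal coordinates of one residue, measured from structure.

    Junction fields (``phi``, ``psi_im1``, ``omega``, ``peptide_bond``,
    ``ca_c_n_angle``, ``c_n_ca_angle``) are ``None`` for the first
    residue, which has no preceding neighbour.
    """

    residue_code: str
    phi: float | None
    psi_im1: float | None
    omega: float | None
    peptide_bond: float | None
    ca_c_n_angle: float | None
    c_n_ca_angle: float | None
    n_ca_length: float
    ca_c_length: float
    c_o_length: float
    n_ca_c_angle: float
    ca_c_o_angle: float
    n_ca_c_o_diangle: float


def extract_backbone_params(pep: Peptide) -> list[BackboneParams]:
    """Measure every backbone internal coordinate of each residue.

    Raises ``ValueError`` naming the residue if the backbone is broken
    (a residue missing any of N, CA, C, O).
    """
    for res in pep:
        if not res.has_complete_backbone:
            raise ValueError(
                f"broken backbone at residue {res.index} ({res.name3}): "
                "missing one of N/CA/C/O"
            )
    out: list[BackboneParams] = []
    seq = pep.sequence
    for i, res in enumerate(pep):
        n, ca, c, o = res["N"], res["CA"], res["C"], res["O"]
        if i == 0:
            phi = psi_im1 = omega = peptide_bond = ca_c_n = c_n_ca = None
        else:
            prev = pep[i - 1]
            pn, pca, pc = prev["N"], prev["CA"], prev["C"]
            psi_im1 = geom.dihedral_angle(pn, pca, pc, n)
            omega = geom.dihedral_angle(pca, pc, n, ca)
            phi = geom.dihedral_angle(pc, n, ca, c)
            peptide_bond = geom.distance(pc, n)
            ca_c_n = geom.bond_angle(pca, pc, n)
            c_n_ca = geom.bond_angle(pc, n, ca)
        out.append(
            BackboneParams(
                residue_code=seq[i],
                phi=phi,
                psi_im1=psi_im1,
                omega=omega,
                peptide_bond=peptide_bond,
                ca_c_n_angle=ca_c_n,
                c_n_ca_angle=c_n_ca,
                n_ca_length=geom.distance(n, ca),
                ca_c_length=geom.distance(ca, c),
                c_o_length=geom.distance(c, o),
                n_ca_c_angle=geom.bond_angle(n, ca, c),
                ca_c_o_angle=geom.bond_angle(ca, c, o),
                n_ca_c_o_diangle=geom.dihedral_angle(n, ca, c, o),
            )
        )
    return out


def reconstruct(sequence: str, params: list[BackboneParams], level: FidelityLevel) -> Peptide:
    """Rebuild a chain from measured backbone parameters at one fidelity level.

    Parameters not selected by ``level`` stay at the residue type's
    defaults; side chains are always built at defaults.  At the two
    dihedral-only levels the carbonyl O dihedral of each non-terminal
    residue is set from the measured psi (O trans to the next nitrogen),
    since O carries no measured-angle information at those levels.
    """
    level = FidelityLevel(level)
    n = len(sequence)
    if len(params) != n:
        raise ValueError(f"params length {len(params)} != sequence length {n}")

    geos = []
    for i, (code, p) in enumerate(zip(sequence, params)):
        g = geometry(code)
        if i > 0:
            g.phi = p.phi
            g.psi_im1 = p.psi_im1
            if level in (
                FidelityLevel.PHI_PSI_OMEGA,
                FidelityLevel.ALL_ANGLES,
                FidelityLevel.ALL_LENGTHS_AND_ANGLES,
            ):
                g.omega = p.omega
        if level in (FidelityLevel.ALL_ANGLES, FidelityLevel.ALL_LENGTHS_AND_ANGLES):
            if i > 0:
                g.CA_C_N_angle = p.ca_c_n_angle
                g.C_N_CA_angle = p.c_n_ca_angle
            g.N_CA_C_angle = p.n_ca_c_angle
            g.CA_C_O_angle = p.ca_c_o_angle
            g.N_CA_C_O_diangle = p.n_ca_c_o_diangle
        else:
            # O trans to the following residue's nitrogen where psi is known
            if i + 1 < n:
                g.N_CA_C_O_diangle = _wrap_angle(params[i + 1].psi_im1 - 180.0)
        if level is FidelityLevel.ALL_LENGTHS_AND_ANGLES:
            if i > 0:
                g.peptide_bond = p.peptide_bond
            g.CA_N_length = p.n_ca_length
            g.CA_C_length = p.ca_c_length
            g.C_O_length = p.c_o_length
        geos.append(g)
    return make_structure_from_geos(geos)


def backbone_rmsd(
    ref: Peptide,
    model: Peptide,
    n_residues: int | None = FULL,
    atom_names=("N", "CA", "C"),
) -> float:
    """Kabsch-superposed RMSD over the backbone trace of the first residues.

    ``n_residues=None`` (``FULL``) scores the whole chain.  Superposition
    is computed on exactly the scored atoms.
    """
    if len(model) < len(ref) and n_residues is FULL:
        raise ValueError("model shorter than reference")
    n = len(ref) if n_residues is FULL else int(n_residues)
    if n > len(ref) or n > len(model):
        raise ValueError(f"n_residues {n} exceeds chain length")
    a = ref.atom_coords(atom_names, n)
    b = model.atom_coords(atom_names, n)
    _, _, rmsd = geom.kabsch_superpose(b, a)
    return rmsd


_PREFIXES = (50, 150, FULL)
_LEVEL_LABEL = {
    FidelityLevel.PHI_PSI: "phi_psi",
    FidelityLevel.PHI_PSI_OMEGA: "phi_psi_omega",
    FidelityLevel.ALL_ANGLES: "all_angles",
    FidelityLevel.ALL_LENGTHS_AND_ANGLES: "all_lengths_and_angles",
}


def reconstruction_report(ref: Peptide, sequence: str | None = None, label: str = "") -> pd.DataFrame:
    """One-row table of reconstruction RMSDs: 4 fidelity levels x 3 prefixes.

    Columns are ``<level>_<prefix>`` with prefixes 50, 150 and ``full``,
    plus the chain length.  Prefixes longer than the chain are reported
    as NaN.  Values are in Angstroms.
    """
    if sequence is None:
        sequence = ref.sequence
    params = extract_backbone_params(ref)
    row: dict[str, object] = {"structure": label, "length": len(ref)}
    for level in FidelityLevel:
        model = reconstruct(sequence, params, level)
        for prefix in _PREFIXES:
            name = "full" if prefix is FULL else str(prefix)
            col = f"{_LEVEL_LABEL[level]}_{name}"
            if prefix is not FULL and prefix > len(ref):
                row[col] = np.nan
            else:
                row[col] = backbone_rmsd(ref, model, prefix)
    return pd.DataFrame([row])
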