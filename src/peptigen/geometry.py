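"""Per-residue internal-coordinate parameter sets (``Geo`` objects).

Every amino-acid type is described by the minimal set of internal
coordinates that uniquely positions each of its heavy atoms: one bond
length, one planar angle and one dihedral per atom, relative to three
previously placed reference atoms.  Parameter names follow a uniform
scheme: bond lengths end in ``_length``, planar angles in ``_angle`` and
dihedrals in ``_diangle``, with the atom path spelled out in the name
(``CA_CB_length``, ``N_CA_CB_angle``, ``C_N_CA_CB_diangle``).

Four backbone parameters deviate from the scheme: the backbone torsions
``phi`` (phi_i of the residue being placed), ``psi_im1`` (psi of the
preceding residue, which positions the incoming nitrogen) and ``omega``
(omega_i), plus ``peptide_bond`` (the C_{i-1}-N_i bond length).

Defaults are ideal-geometry values (Engh & Huber style bond lengths and
angles), with the backbone torsions defaulting to the extended
conformation phi = -120, psi = 140, omega = 180 degrees.  Default chi
rotamers are a fixed per-type table approximating the most common
side-chain conformer at an extended backbone.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Geo",
    "geometry",
    "set_rotamers",
    "format_geometry",
    "read_geometry",
    "random_geometry",
    "AMINO_ACIDS",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
    "SidechainAtom",
    "sidechain_topology",
]

# default extended-conformation backbone torsions
DEFAULT_PHI = -120.0
DEFAULT_PSI_IM1 = 140.0
DEFAULT_OMEGA = 180.0

# backbone ideal geometry (Angstroms / degrees); per-type overrides below
_BACKBONE_DEFAULTS = {
    "peptide_bond": 1.329,
    "CA_N_length": 1.458,
    "CA_C_length": 1.525,
    "C_O_length": 1.231,
    "CA_C_N_angle": 116.2,
    "C_N_CA_angle": 121.7,
    "N_CA_C_angle": 111.2,
    "CA_C_O_angle": 120.8,
    # O trans to the nitrogen of the following residue at the default psi:
    # N_CA_C_O = psi - 180 = -40 for psi = 140
    "N_CA_C_O_diangle": -40.0,
}

_BACKBONE_OVERRIDES = {
    "G": {"CA_N_length": 1.451, "CA_C_length": 1.516, "N_CA_C_angle": 112.5},
    "P": {"CA_N_length": 1.466, "C_N_CA_angle": 122.6, "N_CA_C_angle": 111.8},
}

# improper torsion C-N-CA-CB that yields L-chirality under the IUPAC
# torsion convention (pinned against an embedded L-alanine model)
_CB_DIANGLE = -122.5


@dataclass(frozen=True)
class SidechainAtom:
    """Placement recipe for one heavy side-chain atom.

    The atom is positioned by ``place_atom(a, b, c, length, angle,
    diangle)`` where ``(a, b, c)`` are names of previously placed atoms
    of the same residue.
    """

    name: str
    refs: tuple  # (a, b, c) atom names
    length: float  # Angstrom
    angle: float  # degrees, planar angle b-c-X
    diangle: float  # degrees, torsion a-b-c-X

    @property
    def length_key(self) -> str:
        return f"{self.refs[2]}_{self.name}_length"

    @property
    def angle_key(self) -> str:
        return f"{self.refs[1]}_{self.refs[2]}_{self.name}_angle"

    @property
    def diangle_key(self) -> str:
        return f"{self.refs[0]}_{self.refs[1]}_{self.refs[2]}_{self.name}_diangle"

    @property
    def element(self) -> str:
        return self.name[0]


def _cb(length=1.530, angle=110.4):
    return SidechainAtom("CB", ("C", "N", "CA"), length, angle, _CB_DIANGLE)


# Side-chain topology: ordered placement recipes plus the chi torsion
# parameter names (chi_1, chi_2, ... in biochemical convention).
# Ring and branch atoms carry fixed dihedrals (0/180/branch offsets) so
# they co-rotate with the chi torsion they hang off.
_SIDECHAINS: dict[str, tuple[str, list[SidechainAtom], list[str]]] = {
    "G": ("GLY", [], []),
    "A": ("ALA", [_cb(1.521, 110.4)], []),
    "S": (
        "SER",
        [_cb(), SidechainAtom("OG", ("N", "CA", "CB"), 1.417, 110.8, -65.0)],
        ["N_CA_CB_OG_diangle"],
    ),
    "C": (
        "CYS",
        [_cb(), SidechainAtom("SG", ("N", "CA", "CB"), 1.808, 113.8, -65.0)],
        ["N_CA_CB_SG_diangle"],
    ),
    "T": (
        "THR",
        [
            _cb(1.540, 111.5),
            SidechainAtom("OG1", ("N", "CA", "CB"), 1.433, 109.5, 60.0),
            SidechainAtom("CG2", ("OG1", "CA", "CB"), 1.521, 110.5, -120.0),
        ],
        ["N_CA_CB_OG1_diangle"],
    ),
    "V": (
        "VAL",
        [
            _cb(1.540, 111.5),
            SidechainAtom("CG1", ("N", "CA", "CB"), 1.521, 110.5, 175.0),
            SidechainAtom("CG2", ("CG1", "CA", "CB"), 1.521, 110.5, 122.5),
        ],
        ["N_CA_CB_CG1_diangle"],
    ),
    "L": (
        "LEU",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.530, 116.3, -65.0),
            SidechainAtom("CD1", ("CA", "CB", "CG"), 1.521, 110.7, 175.0),
            SidechainAtom("CD2", ("CD1", "CB", "CG"), 1.521, 110.7, 122.5),
        ],
        ["N_CA_CB_CG_diangle", "CA_CB_CG_CD1_diangle"],
    ),
    "I": (
        "ILE",
        [
            _cb(1.540, 111.5),
            SidechainAtom("CG1", ("N", "CA", "CB"), 1.530, 110.4, -65.0),
            SidechainAtom("CG2", ("CG1", "CA", "CB"), 1.521, 110.5, -122.5),
            SidechainAtom("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, 170.0),
        ],
        ["N_CA_CB_CG1_diangle", "CA_CB_CG1_CD1_diangle"],
    ),
    "M": (
        "MET",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.520, 114.1, -65.0),
            SidechainAtom("SD", ("CA", "CB", "CG"), 1.803, 112.7, 180.0),
            SidechainAtom("CE", ("CB", "CG", "SD"), 1.791, 100.9, -70.0),
        ],
        ["N_CA_CB_CG_diangle", "CA_CB_CG_SD_diangle", "CB_CG_SD_CE_diangle"],
    ),
    "P": (
        "PRO",
        [
            _cb(1.530, 103.0),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.492, 104.5, -25.0),
            SidechainAtom("CD", ("CA", "CB", "CG"), 1.503, 106.1, 40.0),
        ],
        ["N_CA_CB_CG_diangle", "CA_CB_CG_CD_diangle"],
    ),
    "F": (
        "PHE",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.502, 113.8, -65.0),
            SidechainAtom("CD1", ("CA", "CB", "CG"), 1.384, 120.8, 90.0),
            SidechainAtom("CD2", ("CD1", "CB", "CG"), 1.384, 120.8, 180.0),
            SidechainAtom("CE1", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
            SidechainAtom("CE2", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
            SidechainAtom("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
        ],
        ["N_CA_CB_CG_diangle", "CA_CB_CG_CD1_diangle"],
    ),
    "Y": (
        "TYR",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.512, 113.9, -65.0),
            SidechainAtom("CD1", ("CA", "CB", "CG"), 1.389, 120.8, 90.0),
            SidechainAtom("CD2", ("CD1", "CB", "CG"), 1.389, 120.8, 180.0),
            SidechainAtom("CE1", ("CB", "CG", "CD1"), 1.382, 121.1, 180.0),
            SidechainAtom("CE2", ("CB", "CG", "CD2"), 1.382, 121.1, 180.0),
            SidechainAtom("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
            SidechainAtom("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
        ],
        ["N_CA_CB_CG_diangle", "CA_CB_CG_CD1_diangle"],
    ),
    "W": (
        "TRP",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.498, 114.0, -65.0),
            SidechainAtom("CD1", ("CA", "CB", "CG"), 1.365, 126.9, 95.0),
            SidechainAtom("CD2", ("CD1", "CB", "CG"), 1.433, 126.8, 180.0),
            SidechainAtom("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
            SidechainAtom("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
            SidechainAtom("CE3", ("CD1", "CG", "CD2"), 1.398, 133.9, 180.0),
            SidechainAtom("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
            SidechainAtom("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
            SidechainAtom("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0),
        ],
        ["N_CA_CB_CG_diangle", "CA_CB_CG_CD1_diangle"],
    ),
    "D": (
        "ASP",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.516, 112.6, -70.0),
            SidechainAtom("OD1", ("CA", "CB", "CG"), 1.249, 118.4, -15.0),
            SidechainAtom("OD2", ("OD1", "CB", "CG"), 1.249, 118.4, 180.0),
        ],
        ["N_CA_CB_CG_diangle", "CA_CB_CG_OD1_diangle"],
    ),
    "N": (
        "ASN",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.516, 112.6, -65.0),
            SidechainAtom("OD1", ("CA", "CB", "CG"), 1.231, 120.8, -40.0),
            SidechainAtom("ND2", ("OD1", "CB", "CG"), 1.328, 116.4, 180.0),
        ],
        ["N_CA_CB_CG_diangle", "CA_CB_CG_OD1_diangle"],
    ),
    "E": (
        "GLU",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.520, 114.1, -65.0),
            SidechainAtom("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            SidechainAtom("OE1", ("CB", "CG", "CD"), 1.249, 118.4, -10.0),
            SidechainAtom("OE2", ("OE1", "CG", "CD"), 1.249, 118.4, 180.0),
        ],
        ["N_CA_CB_CG_diangle", "CA_CB_CG_CD_diangle", "CB_CG_CD_OE1_diangle"],
    ),
    "Q": (
        "GLN",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.520, 114.1, -65.0),
            SidechainAtom("CD", ("CA", "CB", "CG"), 1.516, 112.6, 180.0),
            SidechainAtom("OE1", ("CB", "CG", "CD"), 1.231, 120.8, 60.0),
            SidechainAtom("NE2", ("OE1", "CG", "CD"), 1.328, 116.4, 180.0),
        ],
        ["N_CA_CB_CG_diangle", "CA_CB_CG_CD_diangle", "CB_CG_CD_OE1_diangle"],
    ),
    "K": (
        "LYS",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.520, 114.1, -65.0),
            SidechainAtom("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
            SidechainAtom("CE", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
            SidechainAtom("NZ", ("CG", "CD", "CE"), 1.489, 111.9, 180.0),
        ],
        [
            "N_CA_CB_CG_diangle",
            "CA_CB_CG_CD_diangle",
            "CB_CG_CD_CE_diangle",
            "CG_CD_CE_NZ_diangle",
        ],
    ),
    "R": (
        "ARG",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.520, 114.1, -65.0),
            SidechainAtom("CD", ("CA", "CB", "CG"), 1.520, 111.3, 180.0),
            SidechainAtom("NE", ("CB", "CG", "CD"), 1.460, 112.0, 180.0),
            SidechainAtom("CZ", ("CG", "CD", "NE"), 1.329, 124.2, 180.0),
            SidechainAtom("NH1", ("CD", "NE", "CZ"), 1.326, 120.3, 0.0),
            SidechainAtom("NH2", ("NH1", "NE", "CZ"), 1.326, 120.3, 180.0),
        ],
        [
            "N_CA_CB_CG_diangle",
            "CA_CB_CG_CD_diangle",
            "CB_CG_CD_NE_diangle",
            "CG_CD_NE_CZ_diangle",
        ],
    ),
    "H": (
        "HIS",
        [
            _cb(),
            SidechainAtom("CG", ("N", "CA", "CB"), 1.497, 113.8, -65.0),
            SidechainAtom("ND1", ("CA", "CB", "CG"), 1.378, 122.7, -75.0),
            SidechainAtom("CD2", ("ND1", "CB", "CG"), 1.356, 129.7, 180.0),
            SidechainAtom("CE1", ("CB", "CG", "ND1"), 1.321, 109.0, 180.0),
            SidechainAtom("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0),
        ],
        ["N_CA_CB_CG_diangle", "CA_CB_CG_ND1_diangle"],
    ),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ONE_TO_THREE = {code: _SIDECHAINS[code][0] for code in AMINO_ACIDS}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


def sidechain_topology(code: str) -> list[SidechainAtom]:
    """Ordered heavy-atom placement recipes for one residue type's side chain."""
    return list(_SIDECHAINS[_check_code(code)][1])


def _check_code(code: str) -> str:
    if not isinstance(code, str) or len(code) != 1:
        raise ValueError(f"amino-acid code must be a single letter, got {code!r}")
    up = code.upper()
    if up not in _SIDECHAINS:
        raise ValueError(f"unknown amino-acid code {code!r}")
    return up


class Geo:
    """Complete internal-coordinate parameter set for one amino-acid type.

    Parameters are plain attributes and can be modified by assignment
    (``geo.phi = -60``).  ``inputRotamers`` sets all chi torsions at once.
    """

    def __init__(self, code: str):
        code = _check_code(code)
        object.__setattr__(self, "_initializing", True)
        self.residue_code = code
        self.residue_name = ONE_TO_THREE[code]
        self.phi = DEFAULT_PHI
        self.psi_im1 = DEFAULT_PSI_IM1
        self.omega = DEFAULT_OMEGA

        params = dict(_BACKBONE_DEFAULTS)
        params.update(_BACKBONE_OVERRIDES.get(code, {}))
        names = ["phi", "psi_im1", "omega", "peptide_bond"]
        self.peptide_bond = params.pop("peptide_bond")
        for key in (
            "CA_N_length",
            "CA_C_length",
            "C_O_length",
            "CA_C_N_angle",
            "C_N_CA_angle",
            "N_CA_C_angle",
            "CA_C_O_angle",
            "N_CA_C_O_diangle",
        ):
            setattr(self, key, params[key])
            names.append(key)

        _, sidechain, chis = _SIDECHAINS[code]
        for atom in sidechain:
            setattr(self, atom.length_key, atom.length)
            setattr(self, atom.angle_key, atom.angle)
            setattr(self, atom.diangle_key, atom.diangle)
            names.extend([atom.length_key, atom.angle_key, atom.diangle_key])
        self._param_names = names
        self._chi_names = list(chis)
        del self._initializing

    # -- introspection -------------------------------------------------
    @property
    def chi_count(self) -> int:
        """Number of chi side-chain torsions for this residue type."""
        return len(self._chi_names)

    @property
    def param_names(self) -> list[str]:
        return list(self._param_names)

    @property
    def chi_names(self) -> list[str]:
        return list(self._chi_names)

    def __setattr__(self, name, value):
        if not name.startswith("_") and not getattr(self, "_initializing", False):
            if name not in ("residue_code", "residue_name") and name not in self._param_names:
                raise AttributeError(
                    f"{self.residue_name} geometry has no parameter {name!r}"
                )
        object.__setattr__(self, name, value)

    # -- behaviour -----------------------------------------------------
    def inputRotamers(self, chis) -> "Geo":
        """Assign all chi torsions at once (chi_1, chi_2, ... order)."""
        chis = list(chis)
        if len(chis) != self.chi_count:
            raise ValueError(
                f"{self.residue_name} expects {self.chi_count} chi angle(s), "
                f"got {len(chis)}"
            )
        for name, value in zip(self._chi_names, chis):
            setattr(self, name, float(value))
        return self

    def copy(self) -> "Geo":
        return _copy.deepcopy(self)

    def to_dict(self) -> dict:
        d = {"residue_code": self.residue_code, "residue_name": self.residue_name}
        for name in self._param_names:
            d[name] = getattr(self, name)
        return d

    def validate(self) -> None:
        """Raise ``ValueError`` if any parameter violates its range."""
        for name in self._param_names:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} is not finite")
            if name.endswith("_length") or name == "peptide_bond":
                if v <= 0:
                    raise ValueError(f"{name} must be > 0, got {v}")
            elif name.endswith("_angle"):
                if not 0 < v < 180:
                    raise ValueError(f"{name} must be in (0, 180), got {v}")
            else:  # dihedral
                if not -180 < v <= 180:
                    raise ValueError(f"{name} must be in (-180, 180], got {v}")

    def __eq__(self, other):
        if not isinstance(other, Geo):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __repr__(self):
        return f"<Geo {self.residue_name} ({self.residue_code})>"

    def __str__(self):
        return format_geometry(self)


def geometry(code: str) -> Geo:
    """Return a fresh default geometry object for one amino-acid type.

    ``code`` is the single-letter amino-acid code (case-insensitive).
    Each call returns an independent object; mutating it never affects
    other instances.
    """
    return Geo(code)


def set_rotamers(geo: Geo, chis) -> Geo:
    """Functional alias for :meth:`Geo.inputRotamers`."""
    return geo.inputRotamers(chis)


def format_geometry(geo: Geo) -> str:
    """Human-readable listing of every parameter, one ``name: value`` per line.

    The output parses back via :func:`read_geometry` (exact round trip).
    """
    lines = [
        f"residue_code: {geo.residue_code}",
        f"residue_name: {geo.residue_name}",
    ]
    lines += [f"{name}: {getattr(geo, name)!r}" for name in geo.param_names]
    return "\n".join(lines) + "\n"


def read_geometry(text: str) -> Geo:
    """Parse the output of :func:`format_geometry` back into a ``Geo``."""
    values: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: expected 'name: value', got {raw!r}")
        key, _, val = line.partition(":")
        values[key.strip()] = val.strip()
    if "residue_code" not in values:
        raise ValueError("geometry listing lacks a residue_code line")
    geo = Geo(values.pop("residue_code"))
    values.pop("residue_name", None)
    for key, val in values.items():
        if key not in geo.param_names:
            raise ValueError(f"unknown geometry parameter {key!r}")
        setattr(geo, key, float(val))
    return geo


def random_geometry(
    code: str,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    length_range: float = 0.02,
    angle_range: float = 5.0,
    diangle_range: float = 5.0,
) -> Geo:
    """A valid ``Geo`` with parameters drawn uniformly around the defaults.

    Bond lengths are perturbed by +/- ``length_range`` Angstroms, planar
    angles by +/- ``angle_range`` degrees and every dihedral (including
    the backbone torsions) by +/- ``diangle_range`` degrees.  Zero-width
    ranges reproduce the defaults exactly.  Deterministic for a fixed
    ``seed`` (or caller-supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if min(length_range, angle_range, diangle_range) < 0:
        raise ValueError("perturbation ranges must be non-negative")
    geo = Geo(code)
    for name in geo.param_names:
        base = getattr(geo, name)
        if name.endswith("_length") or name == "peptide_bond":
            if length_range >= base:
                raise ValueError(
                    f"length_range {length_range} would allow non-positive {name}"
                )
            lo, hi = base - length_range, base + length_range
        elif name.endswith("_angle"):
            if angle_range >= min(base, 180.0 - base):
                raise ValueError(
                    f"angle_range {angle_range} would push {name} out of (0, 180)"
                )
            lo, hi = base - angle_range, base + angle_range
        else:
            lo, hi = base - diangle_range, base + diangle_range
        value = float(rng.uniform(lo, hi))
        if not name.endswith(("_length", "_angle")) and name != "peptide_bond":
            value = _wrap_angle(value)
        setattr(geo, name, value)
    geo.validate()
    return geo


def _wrap_angle(a: float) -> float:
    """Wrap a torsion into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a
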