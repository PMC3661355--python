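"""Synthetic chain generator standing in for crystal-structure test sets.

Generates random-but-valid residue geometries and random-torsion chains
so the whole reconstruction evaluation runs offline.  Every geometry and
torsion the generator drew is returned alongside the built chain, so
extraction can be checked against the generating values exactly.
"""

from __future__ import annotations

import numpy as np

from .builder import Peptide, make_structure_from_geos
from .geometry import AMINO_ACIDS, Geo, random_geometry

__all__ = ["generate_random_chain"]

# minimum |phi| in degrees: near-zero phi puts the backbone in a
# sterically absurd eclipsed state and is excluded from the draw
_PHI_EXCLUSION = 20.0


def generate_random_chain(
    n: int,
    seed: int | None = None,
    sequence: str | None = None,
    length_range: float = 0.02,
    angle_range: float = 5.0,
) -> tuple[list[Geo], Peptide]:
    """Build a random ``n``-residue chain; return its geometries and the chain.

    Each residue gets ideal-geometry parameters perturbed uniformly by
    +/- ``length_range`` Angstroms (bond lengths) and +/- ``angle_range``
    degrees (planar angles and fixed dihedrals), and fresh backbone
    torsions: phi uniform over (-180, 180] excluding |phi| < 20 degrees,
    psi_im1 and omega uniform over (-180, 180].  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n))
    elif len(sequence) != n:
        raise ValueError(f"sequence length {len(sequence)} != n = {n}")

    geos: list[Geo] = []
    for code in sequence:
        g = random_geometry(
            code,
            rng=rng,
            length_range=length_range,
            angle_range=angle_range,
            diangle_range=angle_range,
        )
        g.phi = _random_phi(rng)
        g.psi_im1 = _uniform_torsion(rng)
        g.omega = _uniform_torsion(rng)
        geos.append(g)
    return geos, make_structure_from_geos(geos)


def _uniform_torsion(rng: np.random.Generator) -> float:
    return float(rng.uniform(-180.0, 180.0))


def _random_phi(rng: np.random.Generator) -> float:
    mag = float(rng.uniform(_PHI_EXCLUSION, 180.0))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    return sign * mag
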