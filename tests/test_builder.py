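"""Peptide construction: atom sets, torsion semantics, convenience builders."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from peptigen import geom
from peptigen.builder import (
    add_residue,
    initialize_res,
    make_extended_structure,
    make_structure,
    make_structure_from_geos,
)
from peptigen.geometry import AMINO_ACIDS, geometry, sidechain_topology
from peptigen.simulate import generate_random_chain

HEAVY_ATOM_COUNTS = {
    "G": 4, "A": 5, "S": 6, "C": 6, "T": 7, "V": 7, "P": 7,
    "L": 8, "I": 8, "D": 8, "N": 8, "M": 8,
    "E": 9, "Q": 9, "K": 9, "H": 10, "F": 11, "R": 11, "Y": 12, "W": 14,
}


def measured_torsions(pep, i):
    """(phi_i, psi_{i-1}, omega_i) for residue i (0-based, i >= 1)."""
    p, r = pep[i - 1], pep[i]
    phi = geom.dihedral_angle(p["C"], r["N"], r["CA"], r["C"])
    psi = geom.dihedral_angle(p["N"], p["CA"], p["C"], r["N"])
    omega = geom.dihedral_angle(p["CA"], p["C"], r["N"], r["CA"])
    return phi, psi, omega


@pytest.mark.parametrize("code", AMINO_ACIDS)
def test_heavy_atom_composition(code):
    """Each residue gets its standard heavy-atom set and no hydrogens."""
    res = initialize_res(code)[0]
    assert len(res.atoms) == HEAVY_ATOM_COUNTS[code]
    assert {"N", "CA", "C", "O"} <= set(res.atoms)
    assert not any(name.startswith("H") for name in res.atoms)


@pytest.mark.parametrize("code", AMINO_ACIDS)
def test_initialize_res_build_and_measure(code):
    """Every parameterized internal coordinate is recovered from the model."""
    g = geometry(code)
    res = initialize_res(g)[0]
    assert geom.distance(res["N"], res["CA"]) == pytest.approx(g.CA_N_length, abs=1e-6)
    assert geom.distance(res["CA"], res["C"]) == pytest.approx(g.CA_C_length, abs=1e-6)
    assert geom.distance(res["C"], res["O"]) == pytest.approx(g.C_O_length, abs=1e-6)
    assert geom.bond_angle(res["N"], res["CA"], res["C"]) == pytest.approx(
        g.N_CA_C_angle, abs=1e-6
    )
    assert geom.bond_angle(res["CA"], res["C"], res["O"]) == pytest.approx(
        g.CA_C_O_angle, abs=1e-6
    )
    assert geom.dihedral_angle(res["N"], res["CA"], res["C"], res["O"]) == pytest.approx(
        g.N_CA_C_O_diangle, abs=1e-6
    )
    for atom in sidechain_topology(code):
        a, b, c = (res[x] for x in atom.refs)
        d = res[atom.name]
        assert geom.distance(c, d) == pytest.approx(getattr(g, atom.length_key), abs=1e-6)
        assert geom.bond_angle(b, c, d) == pytest.approx(getattr(g, atom.angle_key), abs=1e-6)
        want = getattr(g, atom.diangle_key)
        got = geom.dihedral_angle(a, b, c, d)
        assert min(abs(got - want), 360 - abs(got - want)) < 1e-6


def test_initialize_res_canonical_frame():
    pep = initialize_res("G")
    res = pep[0]
    assert np.allclose(res["N"], [0, 0, 0])
    assert res["CA"][0] > 0 and np.allclose(res["CA"][1:], 0)
    assert res["C"][2] == pytest.approx(0.0) and res["C"][1] > 0


def test_extended_pentaglycine_torsions():
    pep = make_extended_structure("GGGGG")
    assert len(pep) == 5
    for i in range(1, 5):
        phi, psi, omega = measured_torsions(pep, i)
        assert phi == pytest.approx(-120.0, abs=1e-6)
        assert psi == pytest.approx(140.0, abs=1e-6)
        assert omega == pytest.approx(180.0, abs=1e-6)


def test_helical_pentaglycine_torsions():
    g = geometry("G")
    g.phi, g.psi_im1 = -60.0, -40.0
    pep = initialize_res(geometry("G"))
    for _ in range(4):
        add_residue(pep, g.copy())
    for i in range(1, 5):
        phi, psi, _ = measured_torsions(pep, i)
        assert phi == pytest.approx(-60.0, abs=1e-6)
        assert psi == pytest.approx(-40.0, abs=1e-6)


def test_helix_is_right_handed():
    """phi=-60/psi=-40 must trace a right-handed alpha helix: successive
    CA-CA-CA-CA pseudo-torsions are positive (around +50 degrees)."""
    pep = make_structure("A" * 8, [-60.0] * 7, [-40.0] * 7)
    cas = [res["CA"] for res in pep]
    for i in range(len(cas) - 3):
        assert geom.dihedral_angle(*cas[i : i + 4]) > 0


def test_add_residue_code_overload_matches_geo_route():
    via_geo = initialize_res("G")
    g = geometry("G")
    g.phi, g.psi_im1 = -60.0, -40.0
    add_residue(via_geo, g)
    via_code = initialize_res("G")
    add_residue(via_code, "G", -60.0, -40.0)
    assert np.allclose(via_geo.atom_coords(("N", "CA", "C", "O")),
                       via_code.atom_coords(("N", "CA", "C", "O")))


def test_add_residue_code_overload_serine():
    pep = initialize_res("G")
    add_residue(pep, "S", -120.0, 140.0)
    assert pep[1].name3 == "SER"
    assert "OG" in pep[1]
    phi, psi, _ = measured_torsions(pep, 1)
    assert phi == pytest.approx(-120.0, abs=1e-6)
    assert psi == pytest.approx(140.0, abs=1e-6)


def test_add_residue_errors():
    from peptigen.builder import Peptide

    with pytest.raises(ValueError):
        add_residue(Peptide(), geometry("G"))
    pep = initialize_res("G")
    with pytest.raises(ValueError):
        add_residue(pep, "X", -60.0, -40.0)
    with pytest.raises(TypeError):
        add_residue(pep, "G", -60.0)  # missing psi


def test_make_structure_dipeptide():
    pep = make_structure("GG", [-60.0], [-40.0])
    phi, psi, _ = measured_torsions(pep, 1)
    assert (phi, psi) == (pytest.approx(-60.0, abs=1e-6), pytest.approx(-40.0, abs=1e-6))


def test_make_structure_matches_extended_builder():
    a = make_structure("GGGGG", [-120.0] * 4, [140.0] * 4)
    b = make_extended_structure("GGGGG")
    assert np.allclose(a.atom_coords(("N", "CA", "C", "O")),
                       b.atom_coords(("N", "CA", "C", "O")))


def test_make_structure_length_mismatch():
    with pytest.raises(ValueError, match="4"):
        make_structure("GGGGG", [-60.0] * 3, [140.0] * 4)


def test_make_structure_random_torsions_recovered(rng):
    seq = "ADKLMNPQRS"
    phis = rng.uniform(30, 170, size=9) * rng.choice([-1, 1], size=9)
    psis = rng.uniform(-175, 175, size=9)
    omegas = rng.uniform(-175, 175, size=9)
    pep = make_structure(seq, phis, psis, omegas)
    for i in range(1, 10):
        phi, psi, omega = measured_torsions(pep, i)
        assert phi == pytest.approx(phis[i - 1], abs=1e-6)
        assert psi == pytest.approx(psis[i - 1], abs=1e-6)
        assert omega == pytest.approx(omegas[i - 1], abs=1e-6)


def test_make_extended_structure_all_twenty():
    pep = make_extended_structure(AMINO_ACIDS)
    assert len(pep) == 20
    for i in range(1, 20):
        phi, psi, _ = measured_torsions(pep, i)
        assert phi == pytest.approx(-120.0, abs=1e-6)
        assert psi == pytest.approx(140.0, abs=1e-6)


def test_make_extended_structure_rejects_bad_code():
    with pytest.raises(ValueError, match="X"):
        make_extended_structure("AXA")


def test_make_structure_from_geos_equivalences():
    assert np.allclose(
        make_structure_from_geos([geometry("G")]).atom_coords(("N", "CA", "C", "O")),
        initialize_res("G").atom_coords(("N", "CA", "C", "O")),
    )
    geos = [geometry(c) for c in "GAS"]
    assert np.allclose(
        make_structure_from_geos(geos).atom_coords(),
        make_extended_structure("GAS").atom_coords(),
    )
    with pytest.raises(ValueError):
        make_structure_from_geos([])


def test_chain_frame_covariance():
    """Transform-then-extend equals extend-then-transform."""
    R = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
    t = np.array([3.0, -1.0, 5.0])
    seed = initialize_res("A")
    moved_first = seed.transformed(R, t)
    add_residue(moved_first, "L", -70.0, 120.0)
    grown_first = initialize_res("A")
    add_residue(grown_first, "L", -70.0, 120.0)
    grown_then_moved = grown_first.transformed(R, t)
    assert np.allclose(
        moved_first.atom_coords(("N", "CA", "C", "O")),
        grown_then_moved.atom_coords(("N", "CA", "C", "O")),
        atol=1e-9,
    )


def test_build_measure_rebuild_idempotence():
    """Extracting internal coordinates from a random chain and rebuilding
    reproduces the chain to numerical precision."""
    from peptigen.reconstruct import (
        FidelityLevel,
        backbone_rmsd,
        extract_backbone_params,
        reconstruct,
    )

    geos, pep = generate_random_chain(25, seed=42)
    params = extract_backbone_params(pep)
    rebuilt = reconstruct(pep.sequence, params, FidelityLevel.ALL_LENGTHS_AND_ANGLES)
    assert backbone_rmsd(pep, rebuilt) <= 1e-3


def test_psi_of_last_residue_is_not_reported():
    """psi_i needs residue i+1; no torsion accessor pretends otherwise."""
    pep = initialize_res("G")
    params = __import__("peptigen").extract_backbone_params(pep)
    assert params[0].psi_im1 is None and params[0].phi is None
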