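# Methods

## Internal-coordinate chain construction

A polypeptide is represented as an ordered list of residues, each an
ordered map of named heavy atoms with Cartesian positions in Å. The
generative model is purely geometric: every atom beyond the first three
of the chain is placed by `place_atom(a, b, c, length, angle, dihedral)`
— given three already-placed reference atoms it returns the unique point
at `length` Å from `c`, forming the planar angle `angle` at `c` with
`b`, and the torsion `dihedral` about the `b→c` axis relative to `a`
(the natural-extension/Z-matrix construction). The placement is exact:
re-measuring any placed atom recovers the three inputs to ≈1e-12, so
accumulated error over a 600-residue chain stays near machine precision
(the guaranteed tolerance is 1e-6 per placement, far below the 0.01 Å
backbone budget for chains of that length).

Residue 1 is built in a canonical frame — N at the origin, CA on +x, C
in the z = 0 half-plane with y > 0. The frame is arbitrary because all
scoring superposes first; a covariance test verifies that rigidly moving
a seed chain and then growing it equals growing and then moving.

Appending residue *i* uses, in order:

| atom placed | references | length | angle | dihedral |
|---|---|---|---|---|
| N_i  | N_{i−1}, CA_{i−1}, C_{i−1} | peptide_bond | CA_C_N_angle | ψ_{i−1} |
| CA_i | CA_{i−1}, C_{i−1}, N_i | CA_N_length | C_N_CA_angle | ω_i |
| C_i  | C_{i−1}, N_i, CA_i | CA_C_length | N_CA_C_angle | φ_i |
| O_i  | N_i, CA_i, C_i | C_O_length | CA_C_O_angle | N_CA_C_O_diangle |

followed by the side-chain atoms of the residue's topology table, each
with its own (length, angle, dihedral) triple. ψ of the final residue is
undefined until another residue exists; no API reports it.

## Conventions

* **Torsion sign**: IUPAC — cis = 0°, trans = +180°, range (−180°, 180°].
  Verified against Bio.PDB's `calc_dihedral` on random quadruples. With
  this convention φ = −60°, ψ = −40° produces a right-handed α-helix
  (checked via the +50° CA-pseudo-torsion signature).
* **Units**: Å and degrees everywhere at the API surface.
* **Chirality**: CB is placed with the improper torsion C-N-CA-CB =
  −122.5°, which yields L-amino acids under the convention above (pinned
  against an independently embedded L-alanine model).
* **Carbonyl O**: parameterised by the dihedral N-CA-C-O
  (`N_CA_C_O_diangle`, default −40° so that O is trans to the next
  nitrogen at the default ψ = 140°). The builder always uses the Geo's
  value, including for the final residue.

## Default geometry

Backbone defaults are ideal-geometry values in the Engh–Huber tradition
(N-CA 1.458 Å, CA-C 1.525 Å, C-O 1.231 Å, C-N 1.329 Å; CA-C-N 116.2°,
C-N-CA 121.7°, N-CA-C 111.2°, CA-C-O 120.8°; glycine and proline carry
small type-specific overrides). Side-chain tables give each heavy atom
one placement triple; branch atoms (e.g. Val CG2, Asp OD2, aromatic ring
closers) are referenced off their sibling so they co-rotate when a χ
torsion changes. Default χ rotamers are a fixed per-type table
approximating the most common conformer at an extended backbone; they
are plausible, not survey-derived, and nothing in the evaluation depends
on their exact values (all reconstruction scoring is backbone-only, and
side-chain correctness is established by build-and-measure round trips,
which hold for any valid parameter values). Ring closure is approximate
by construction (each ring atom is placed once, from one path); closure
gaps with default parameters are ≤0.02 Å for the aromatic rings. Proline
gets a full topology like any other type; no ring-closure constraint
ties CD back to N.

## Reconstruction evaluation

`extract_backbone_params` measures per residue: φ, ψ_{i−1}, ω, the
peptide bond length, the planar angles CA-C-N, C-N-CA, N-CA-C, CA-C-O,
the O dihedral N-CA-C-O and the lengths N-CA, CA-C, C-O — everything the
builder consumes. `reconstruct` rebuilds the sequence applying the
measured values selected by the fidelity level (φψ; φψω; all angles; all
lengths and angles), leaving the rest at defaults; side chains are
always default. At the two dihedral-only levels the O dihedral of
non-terminal residues is set from the measured ψ (O trans to the next N)
rather than the default — O is not scored, so this only keeps models
chemically sensible.

RMSD is computed over the N, CA, C trace (O excluded so the O-dihedral
convention cannot confound the score; `backbone_rmsd(..., atom_names=)`
can include it), after Kabsch superposition computed on exactly the
scored atoms — prefix scores (first 50 / first 150 residues) superpose
on the prefix itself. Superposition uses
`scipy.spatial.transform.Rotation.align_vectors` after centroid removal
and is cross-checked against Bio.PDB's `SVDSuperimposer` in the tests.

## Synthetic test chains

`generate_random_chain` stands in for a crystal-structure test set so
the whole evaluation runs offline. Per residue it draws ideal-geometry
parameters perturbed uniformly by ±0.02 Å (bond lengths) and ±5°
(planar angles and fixed dihedrals), then fresh backbone torsions: φ
uniform over (−180°, 180°] excluding |φ| < 20° (a sterically absurd
eclipsed region), ψ and ω uniform over (−180°, 180°]. These ranges make
the four fidelity levels separate cleanly: on 200-residue chains the
median full-chain RMSD falls from tens of Å (φψ only, since the true ω
is far from the default) through a few Å (φψω) to ~0.2 Å (all angles)
to ~1e-12 (everything measured).

What the generator does **not** emulate: real Ramachandran statistics,
secondary structure, excluded volume (chains may self-intersect),
correlated deviations from ideal geometry, missing residues or altlocs.
Passing tests therefore demonstrate the correctness of the
geometry→coordinates machinery and the information content of each
parameter class — not predictive accuracy on real proteins, for which
the reconstruction CLI can be run on any deposited PDB chain.

Problem sizes used in the shipped checks: a tripeptide and a
600-residue chain for exactness bounds, twenty 200-residue chains for
the fidelity-ordering comparison.

## Numerical and design choices

* Degenerate input (coincident/collinear references, non-positive
  lengths, angles outside (0°, 180°)) raises a dedicated error; nothing
  is silently clamped except the arccos argument in angle measurement
  (clipped to [−1, 1] against rounding).
* PDB writing rounds coordinates to 3 decimals (the format's width);
  write→read→write is byte-identical, and the quantisation perturbs
  re-measured torsions by <0.1°.
* The PDB reader keeps the first model and first alternate location,
  skips HETATM and hydrogens, rejects insertion codes (they would break
  the sequential-backbone assumption), and truncates — rather than skips
  past — the first residue with an incomplete backbone, because
  reconstruction needs an unbroken chain.
* No OXT terminal atom and no hydrogens are ever placed.
* `make_structure`'s angle lists have length n−1: element k
  parameterises the junction placing residue k+2 (its φ, the preceding
  ψ), matching the ψ_{i−1} semantics of residue addition.

## Known limitations

Proline's ring is not closed (CD–N distance with default parameters is
~1.5 Å rather than the ideal ~1.47 Å bond, and nothing constrains it
under parameter changes). Rotamer defaults are fixed, not
backbone-dependent. Only single chains are handled; no mmCIF, no
multi-model ensembles beyond taking the first model. Reconstruction of
*real* structures at dihedral-only fidelity is chaotic by nature — small
convention or default differences change the large RMSD values
substantially, which is why those values are only meaningful to a few
tenths of an Å.
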