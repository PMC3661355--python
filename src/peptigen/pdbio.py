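"""Fixed-column PDB reading and writing for single protein chains.

The writer emits one ATOM record per heavy atom in residue/placement
order, serials from 1, coordinates rounded to 3 decimals, occupancy 1.00
and B-factor 0.00, closed by TER and END.  write -> read -> write is
byte-identical.

The reader keeps the first MODEL only, skips HETATM records and
hydrogens, keeps only the first alternate location of each atom, rejects
insertion codes, and truncates the chain at the first residue whose
backbone (N, CA, C, O) is incomplete (reconstruction needs an unbroken
backbone; a warning is logged).  Gzipped files are accepted
transparently by path suffix.
"""

from __future__ import annotations

import gzip
import io
import logging
import urllib.request
from pathlib import Path

from .builder import Peptide, Residue
from .geometry import THREE_TO_ONE

__all__ = ["write_pdb", "read_pdb_chain", "PdbFormatError", "fetch_pdb"]

logger = logging.getLogger(__name__)


class PdbFormatError(ValueError):
    """Raised for records that violate the fixed-column PDB format."""


_ATOM_FMT = (
    "ATOM  {serial:5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
    "{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}  \n"
)
_TER_FMT = "TER   {serial:5d}      {resname:>3s} {chain:1s}{resseq:4d}\n"


def _atom_field(name: str) -> str:
    # names up to 3 characters start in column 14 (blank column 13)
    return f" {name:<3s}" if len(name) < 4 else name


def write_pdb(pep: Peptide, sink) -> None:
    """Write a peptide as PDB ATOM records to a path or text file object."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            write_pdb(pep, fh)
        return
    serial = 0
    last = None
    for res in pep:
        for atom in res.atoms.values():
            serial += 1
            x, y, z = atom.position
            sink.write(
                _ATOM_FMT.format(
                    serial=serial,
                    name=_atom_field(atom.name),
                    altloc=" ",
                    resname=res.name3,
                    chain=pep.chain_id,
                    resseq=res.index,
                    icode=" ",
                    x=x,
                    y=y,
                    z=z,
                    occ=1.00,
                    b=0.00,
                    element=atom.element,
                )
            )
        last = res
    if last is not None:
        sink.write(
            _TER_FMT.format(
                serial=serial + 1, resname=last.name3, chain=pep.chain_id, resseq=last.index
            )
        )
    sink.write("END\n")


def pdb_string(pep: Peptide) -> str:
    """The PDB text for a peptide, as written by :func:`write_pdb`."""
    buf = io.StringIO()
    write_pdb(pep, buf)
    return buf.getvalue()


def _open_source(source):
    if isinstance(source, (str, Path)):
        p = str(source)
        if p.endswith(".gz"):
            return gzip.open(p, "rt")
        return open(p)
    return source


def _parse_atom_line(line: str, lineno: int):
    try:
        return {
            "name": line[12:16].strip(),
            "altloc": line[16:17].strip(),
            "resname": line[17:20].strip(),
            "chain": line[21:22],
            "resseq": int(line[22:26]),
            "icode": line[26:27].strip(),
            "x": float(line[30:38]),
            "y": float(line[38:46]),
            "z": float(line[46:54]),
            "element": line[76:78].strip() if len(line) >= 78 else "",
        }
    except (ValueError, IndexError) as exc:
        raise PdbFormatError(f"line {lineno}: unparseable ATOM record: {exc}") from exc


def _is_hydrogen(name: str, element: str) -> bool:
    if element:
        return element.upper() in ("H", "D")
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() in ("H", "D")


def read_pdb_chain(source, chain_id: str = "A") -> Peptide:
    """Read one protein chain from PDB text into a :class:`Peptide`.

    ``source`` is a path (``.gz`` accepted) or an open text stream.
    Raises ``KeyError`` if the chain is absent and :class:`PdbFormatError`
    for malformed records or insertion codes.
    """
    fh = _open_source(source)
    close = fh is not source
    try:
        raw_residues: list[tuple[int, str, dict]] = []  # (resseq, resname, atoms)
        seen_chain = False
        for lineno, line in enumerate(fh, 1):
            rec = line[:6]
            if rec in ("ENDMDL",):
                break  # first model only
            if rec != "ATOM  ":
                continue
            a = _parse_atom_line(line, lineno)
            if a["chain"] != chain_id:
                continue
            seen_chain = True
            if a["icode"]:
                raise PdbFormatError(
                    f"line {lineno}: insertion code {a['icode']!r} not supported"
                )
            if _is_hydrogen(a["name"], a["element"]):
                continue
            if not raw_residues or raw_residues[-1][0] != a["resseq"]:
                raw_residues.append((a["resseq"], a["resname"], {}))
            _, resname, atoms = raw_residues[-1]
            if resname != a["resname"]:
                raise PdbFormatError(
                    f"line {lineno}: residue {a['resseq']} has conflicting names "
                    f"{resname}/{a['resname']}"
                )
            if a["name"] in atoms:
                continue  # later altloc of an already-seen atom
            atoms[a["name"]] = (a["x"], a["y"], a["z"])
    finally:
        if close:
            fh.close()

    if not seen_chain:
        raise KeyError(f"chain {chain_id!r} not found")

    pep = Peptide(chain_id)
    for resseq, resname, atoms in raw_residues:
        complete = all(k in atoms for k in ("N", "CA", "C", "O"))
        known = resname in THREE_TO_ONE
        if not (complete and known):
            reason = "incomplete backbone" if known else f"nonstandard residue {resname}"
            logger.warning(
                "chain %s truncated at residue %s (%s): %s",
                chain_id,
                resseq,
                resname,
                reason,
            )
            break
        res = Residue(resname, len(pep) + 1)
        for name, xyz in atoms.items():
            res.add_atom(name, xyz)
        pep.append(res)
    if len(pep) == 0:
        raise PdbFormatError(f"chain {chain_id!r} has no usable residues")
    return pep


def fetch_pdb(pdb_id: str, dest_dir, timeout: float = 30.0) -> Path:
    """Download one PDB entry from RCSB into ``dest_dir`` (network required).

    Returns the path to the downloaded ``.pdb`` file; reuses an existing
    file if present.
    """
    pdb_id = pdb_id.lower()
    dest = Path(dest_dir) / f"{pdb_id}.pdb"
    if dest.exists():
        return dest
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest
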