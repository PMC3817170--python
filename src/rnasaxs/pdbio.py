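"""PDB reading/writing for reduced-representation RNA models and fragments.

Models are written as standard ATOM records (chain A, 1-based residue
numbering); the base pseudo-atom is emitted as N9 for purines and N1 for
pyrimidines.  Reading accepts arbitrary RNA PDB files and extracts the
reduced atom set; missing atoms become NaN coordinates.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from . import geometry as geo

RNA_RESNAMES = {"A", "U", "G", "C", "RA", "RU", "RG", "RC",
                "ADE", "URA", "URI", "GUA", "CYT"}
_RESNAME_TO_BASE = {"A": "A", "RA": "A", "ADE": "A", "U": "U", "RU": "U",
                    "URA": "U", "URI": "U", "G": "G", "RG": "G", "GUA": "G",
                    "C": "C", "RC": "C", "CYT": "C"}
PURINES = {"A", "G"}


class PdbFormatError(ValueError):
    """File contains no usable RNA atoms."""


def _n_atom_name(base: str) -> str:
    return "N9" if base in PURINES else "N1"


def write_pdb(path, model, remark: str | None = None) -> None:
    """Write an :class:`~rnasaxs.assembly.RnaModel` as a PDB file."""
    lines = []
    if remark:
        lines.append(f"REMARK   6 {remark}")
    serial = 1
    for res in range(model.n_residues):
        base = model.sequence[res]
        for ai, name in enumerate(geo.ATOM_NAMES):
            xyz = model.coords[res, ai]
            if np.any(np.isnan(xyz)):
                continue
            pdb_name = _n_atom_name(base) if name == "N" else name
            element = pdb_name[0]
            lines.append(
                f"ATOM  {serial:5d} {pdb_name:<4s} {base:>2s} A{res + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path, model_index: int = 0):
    """Read an RNA PDB file into an :class:`~rnasaxs.assembly.RnaModel`.

    The first altloc of each atom is kept; for multi-MODEL files
    ``model_index`` selects the model (default: first).  Residues are
    taken in file order across chains; atoms outside the reduced
    representation are ignored and absent reduced atoms are NaN.
    """
    from .assembly import RnaModel  # local import to avoid a cycle

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise PdbFormatError(f"{path}: no models")
    model_index = min(model_index, len(st) - 1)
    gmodel = st[model_index]
    sequence = []
    coords = []
    for chain in gmodel:
        for residue in chain.first_conformer():
            name = residue.name.strip().upper()
            if name not in RNA_RESNAMES:
                continue
            base = _RESNAME_TO_BASE[name]
            res_coords = np.full((geo.N_ATOMS, 3), np.nan)
            for atom in residue:
                aname = atom.name.strip().replace("*", "'")
                if aname in ("N9", "N1") and aname == _n_atom_name(base):
                    aname = "N"
                idx = geo.ATOM_INDEX.get(aname)
                if idx is not None:
                    res_coords[idx] = [atom.pos.x, atom.pos.y, atom.pos.z]
            if np.all(np.isnan(res_coords)):
                continue
            sequence.append(base)
            coords.append(res_coords)
    if not coords:
        raise PdbFormatError(f"{path}: no RNA atoms found")
    return RnaModel("".join(sequence), np.array(coords))


def write_fragment_pdb(path, fragment) -> None:
    """Fragment file: one MODEL per strand, residues numbered within strand."""
    lines = []
    serial = 1
    for si, sl in enumerate(fragment.strand_slices()):
        lines.append(f"MODEL     {si + 1:4d}")
        seq = fragment.sequences[si]
        for local, res in enumerate(range(sl.start, sl.stop)):
            base = seq[local] if local < len(seq) else "N"
            for ai, name in enumerate(geo.ATOM_NAMES):
                xyz = fragment.coords[res, ai]
                pdb_name = _n_atom_name(base) if name == "N" else name
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name:<4s} {base:>2s} A{local + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {pdb_name[0]:>2s}")
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fragment_pdb(path) -> np.ndarray:
    """Read fragment coordinates written by :func:`write_fragment_pdb`."""
    st = gemmi.read_structure(str(path))
    coords = []
    for gmodel in st:
        for chain in gmodel:
            for residue in chain:
                res_coords = np.full((geo.N_ATOMS, 3), np.nan)
                for atom in residue:
                    aname = atom.name.strip().replace("*", "'")
                    if aname in ("N9", "N1"):
                        aname = "N"
                    idx = geo.ATOM_INDEX.get(aname)
                    if idx is not None:
                        res_coords[idx] = [atom.pos.x, atom.pos.y, atom.pos.z]
                coords.append(res_coords)
    return np.array(coords) if coords else np.empty((0, geo.N_ATOMS, 3))
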