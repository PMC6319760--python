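"""Reference-structure handling: PDB input, residue bookkeeping, group and CDR annotation.

The reference (native) structure anchors every contact definition downstream.
Internally residues are indexed 0-based and contiguously; author numbering
(sequence id + insertion code, e.g. ``Trp47``) is retained for reports.
Coordinates are in Angstrom throughout the package.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ResidueGroupScheme",
    "DEFAULT_SCHEME",
    "STANDARD_RESIDUES",
    "load_structure",
    "write_pdb",
    "classify_residue",
    "annotate_cdrs",
    "StructureError",
    "UnknownResidueError",
]

# Residue names treated as terminal capping groups: their atoms are merged
# into the adjacent amino-acid residue for contact purposes and they never
# appear as residues of their own in reports.
CAP_RESIDUES = {"NME", "NMA", "ACE"}
WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_RESIDUES = tuple(sorted(THREE_TO_ONE))


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structures/annotations."""


class UnknownResidueError(KeyError):
    """Raised when a residue name is absent from a residue-group scheme."""


@dataclasses.dataclass(frozen=True)
class Atom:
    """A single atom of the reference structure.

    ``residue_index`` is the internal 0-based contiguous index; ``is_cap``
    marks atoms contributed by a terminal capping group (merged into the
    terminal residue for contact purposes, excluded from per-residue tables).
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    xyz: np.ndarray
    is_cap: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclasses.dataclass(frozen=True)
class Residue:
    index: int
    name: str
    author_seq_id: int
    insertion_code: str
    chain_id: str

    @property
    def label(self) -> str:
        """Human-readable author-numbered label, e.g. ``Trp47`` or ``Tyr100A``."""
        nice = self.name.capitalize()
        return f"{nice}{self.author_seq_id}{self.insertion_code.strip()}"


class StructureModel:
    """Atoms of a reference structure with residue bookkeeping.

    Parameters
    ----------
    atoms : ordered list of :class:`Atom`
    residues : ordered list of :class:`Residue` with contiguous 0-based indices
    source_id : identifier of the source (PDB id, file stem, generator tag)
    cdr_ranges : optional list of ``(start_index, end_index)`` residue spans
        (inclusive, internal indices) marking CDR loops.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        residues: Sequence[Residue],
        source_id: str = "",
        cdr_ranges: Optional[Sequence[tuple[int, int]]] = None,
    ) -> None:
        if not atoms:
            raise StructureError("structure contains no atoms")
        self.atoms = list(atoms)
        self.residues = list(residues)
        self.source_id = source_id
        self.cdr_ranges = list(cdr_ranges) if cdr_ranges else []
        self._validate()
        self._coords: Optional[np.ndarray] = None

    def _validate(self) -> None:
        for i, res in enumerate(self.residues):
            if res.index != i:
                raise StructureError("residue indices must be contiguous from 0")
        n = len(self.residues)
        for atom in self.atoms:
            if not (0 <= atom.residue_index < n):
                raise StructureError(
                    f"atom {atom.serial} maps to no residue ({atom.residue_index})"
                )
            if not np.all(np.isfinite(atom.xyz)):
                raise StructureError(f"atom {atom.serial} has non-finite coordinates")

    # -- coordinates ----------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float64 array of coordinates in Angstrom."""
        if self._coords is None:
            self._coords = np.array([a.xyz for a in self.atoms], dtype=np.float64)
        return self._coords

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def heavy_atom_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=np.intp
        )

    def heavy_atoms(self) -> list[Atom]:
        """All non-hydrogen atoms (waters/heteroatoms were dropped at load)."""
        return [a for a in self.atoms if not a.is_hydrogen]

    def atoms_of_residue(self, residue_index: int) -> list[Atom]:
        return [a for a in self.atoms if a.residue_index == residue_index]

    def residue_names(self) -> list[str]:
        return [r.name for r in self.residues]

    def residue_label(self, residue_index: int) -> str:
        return self.residues[residue_index].label

    # -- CDR annotation -------------------------------------------------
    def in_cdr(self, residue_index: int) -> bool:
        return any(s <= residue_index <= e for s, e in self.cdr_ranges)

    def which_cdr(self, residue_index: int) -> Optional[int]:
        for k, (s, e) in enumerate(self.cdr_ranges):
            if s <= residue_index <= e:
                return k + 1
        return None


@dataclasses.dataclass(frozen=True)
class ResidueGroupScheme:
    """Partition of residue types into physicochemical groups.

    The default groups follow the hydrophilic / hydrophobic / small
    classification commonly used for contact-map decomposition of antibody
    domains: hydrophilic = Asp, Glu, Gln, Asn, Arg, Lys, His; hydrophobic =
    Phe, Tyr, Trp, Leu, Val, Ile, Met, Cys, Pro; small = Gly, Ala, Ser, Thr.
    """

    mapping: dict
    name: str = "default"

    GROUPS = ("hydrophilic", "hydrophobic", "small")

    def classify(self, residue_name: str) -> str:
        try:
            return self.mapping[residue_name.upper()]
        except KeyError:
            raise UnknownResidueError(
                f"residue name {residue_name!r} is not covered by scheme "
                f"{self.name!r}"
            ) from None

    def members(self, group: str) -> list[str]:
        return sorted(k for k, v in self.mapping.items() if v == group)


def _default_mapping() -> dict:
    groups = {
        "hydrophilic": ["ASP", "GLU", "GLN", "ASN", "ARG", "LYS", "HIS"],
        "hydrophobic": ["PHE", "TYR", "TRP", "LEU", "VAL", "ILE", "MET", "CYS", "PRO"],
        "small": ["GLY", "ALA", "SER", "THR"],
    }
    return {res: g for g, names in groups.items() for res in names}


DEFAULT_SCHEME = ResidueGroupScheme(mapping=_default_mapping(), name="default")


def classify_residue(residue_name: str, scheme: ResidueGroupScheme = DEFAULT_SCHEME) -> str:
    """Return the group label of a 3-letter residue name under ``scheme``.

    Raises :class:`UnknownResidueError` for names outside the scheme — never
    a silent default.
    """
    return scheme.classify(residue_name)


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str, bp_element: str) -> str:
    el = (bp_element or "").strip().upper()
    if el:
        return el
    # Fall back on the atom-name convention: columns 13-14 hold the element,
    # names like "1HB1"/"HG21" are hydrogens.
    stripped = atom_name.strip()
    if stripped and stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H":
        return "H"
    two = stripped[:2].upper()
    if two in ("CL", "BR", "FE", "ZN", "MG", "NA", "MN", "SE"):
        return two
    return stripped[0].upper()


def _pick_altloc(bp_atom):
    """Resolve a possibly disordered atom to the highest-occupancy altloc.

    Ties are broken by file order (first wins).
    """
    if not bp_atom.is_disordered():
        return bp_atom
    children = bp_atom.disordered_get_list()
    best = children[0]
    for child in children[1:]:
        occ_b = best.get_occupancy() or 0.0
        occ_c = child.get_occupancy() or 0.0
        if occ_c > occ_b:
            best = child
    return best


def load_structure(
    path,
    model_index: int = 0,
    source_id: Optional[str] = None,
    keep_hetero: bool = False,
) -> StructureModel:
    """Read a reference structure from a PDB file.

    Waters, ions and other heteroatoms are dropped (``keep_hetero=True``
    retains non-water heteroatoms, useful for RMSD debugging).  Altlocs are
    resolved to the highest occupancy, ties to the first.  Terminal capping
    groups (ACE/NME) are merged into the adjacent amino-acid residue and
    their atoms flagged ``is_cap``.

    Parameters
    ----------
    path : PDB file path
    model_index : which MODEL to take (0-based)
    """
    from Bio.PDB import PDBParser  # deferred: keeps import cost off the hot path

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        bp_structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # noqa: BLE001 - wrap parser failures uniformly
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(bp_structure.get_models())
    if not models:
        raise StructureError(f"{path} contains no models")
    if not (0 <= model_index < len(models)):
        raise StructureError(
            f"model_index {model_index} out of range (file has {len(models)} models)"
        )
    bp_model = models[model_index]

    atoms: list[Atom] = []
    residues: list[Residue] = []
    # Gather residues in file order first so caps can be merged into neighbours.
    raw: list[tuple] = []  # (chain_id, resname, seqid, icode, [bp_atoms], is_cap)
    for chain in bp_model:
        for res in chain:
            hetfield, seqid, icode = res.id
            resname = res.get_resname().strip().upper()
            if resname in WATER_RESIDUES or hetfield.startswith("W"):
                continue
            is_cap = resname in CAP_RESIDUES
            if hetfield.strip() and not is_cap and not keep_hetero:
                continue
            # iterating the residue yields DisorderedAtom wrappers, one per
            # atom name; resolve each to its best altloc
            bp_atoms = [_pick_altloc(a) for a in res]
            raw.append((chain.id, resname, seqid, icode, bp_atoms, is_cap))

    if not raw:
        raise StructureError(f"{path} contains no protein atoms")

    # Merge capping groups into the adjacent residue (ACE -> following,
    # NME -> preceding).
    merged: list[tuple] = []
    pending_cap_atoms: list = []
    for entry in raw:
        chain_id, resname, seqid, icode, bp_atoms, is_cap = entry
        if is_cap:
            if resname == "ACE":
                pending_cap_atoms.extend(bp_atoms)
            else:  # NME/NMA: attach to the previous residue
                if merged:
                    merged[-1][4].extend([("CAP", a) for a in bp_atoms])
                # a leading NME with no predecessor is dropped
            continue
        tagged = [("RES", a) for a in bp_atoms]
        if pending_cap_atoms:
            tagged = [("CAP", a) for a in pending_cap_atoms] + tagged
            pending_cap_atoms = []
        merged.append([chain_id, resname, seqid, icode, tagged, False])

    if not merged:
        raise StructureError(f"{path} contains no non-cap protein residues")

    serial = 0
    for res_index, (chain_id, resname, seqid, icode, tagged, _) in enumerate(merged):
        residues.append(Residue(res_index, resname, int(seqid), icode or " ", chain_id))
        for tag, bp_atom in tagged:
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name=bp_atom.get_name(),
                    element=_guess_element(bp_atom.get_name(), bp_atom.element),
                    residue_index=res_index,
                    residue_name=resname,
                    chain_id=chain_id,
                    xyz=np.asarray(bp_atom.get_coord(), dtype=np.float64),
                    is_cap=(tag == "CAP"),
                )
            )

    return StructureModel(
        atoms=atoms,
        residues=residues,
        source_id=source_id if source_id is not None else path.stem,
    )


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: element symbol right-aligned in columns 13-14 for
    # single-letter elements, so 1-3 character names get a leading space.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(structure: StructureModel, path, frames: Optional[Iterable[np.ndarray]] = None) -> None:
    """Write a structure (or a multi-model trajectory of it) as PDB.

    ``frames``, if given, is an iterable of (n_atoms, 3) coordinate arrays
    (Angstrom); each becomes one MODEL sharing the structure's topology.
    Coordinates are written with the format's 3-decimal precision.
    """
    path = Path(path)

    def _records(coords: np.ndarray) -> list[str]:
        lines = []
        for atom, xyz in zip(structure.atoms, coords):
            res = structure.residues[atom.residue_index]
            lines.append(
                "ATOM  {serial:>5d} {name} {resname:<3s} {chain}{seq:>4d}{icode}"
                "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                    serial=atom.serial % 100000,
                    name=_format_atom_name(atom.name, atom.element),
                    resname=(atom.residue_name if not atom.is_cap else atom.residue_name)[:3],
                    chain=res.chain_id[:1] or "A",
                    seq=res.author_seq_id,
                    icode=(res.insertion_code or " ")[:1],
                    x=xyz[0], y=xyz[1], z=xyz[2],
                    occ=1.00, b=0.00,
                    el=atom.element[:2],
                )
            )
        return lines

    with open(path, "w") as fh:
        fh.write(f"REMARK   1 written by qstab source_id={structure.source_id}\n")
        if frames is None:
            fh.writelines(_records(structure.coords))
            fh.write("END\n")
        else:
            for m, coords in enumerate(frames, start=1):
                coords = np.asarray(coords, dtype=np.float64)
                if coords.shape != (structure.n_atoms, 3):
                    raise StructureError(
                        f"frame {m} has shape {coords.shape}, expected "
                        f"({structure.n_atoms}, 3)"
                    )
                fh.write(f"MODEL     {m:>4d}\n")
                fh.writelines(_records(coords))
                fh.write("ENDMDL\n")
            fh.write("END\n")


# ---------------------------------------------------------------------------
# CDR annotation
# ---------------------------------------------------------------------------

_SPAN_RE = re.compile(r"^(?P<name>[A-Za-z]{3})?\s*(?P<seq>-?\d+)(?P<icode>[A-Za-z]?)$")


def _resolve_endpoint(structure: StructureModel, endpoint) -> int:
    """Resolve an author-numbering endpoint to an internal residue index.

    Accepts an int author seq id, a string like ``"23"``, ``"Leu23"`` or
    ``"Tyr100A"`` (insertion code).  When a residue name is given it is
    checked against the structure.
    """
    if isinstance(endpoint, (int, np.integer)):
        name, seq, icode = None, int(endpoint), ""
    else:
        m = _SPAN_RE.match(str(endpoint).strip())
        if not m:
            raise StructureError(f"cannot parse CDR endpoint {endpoint!r}")
        name = m.group("name")
        seq = int(m.group("seq"))
        icode = m.group("icode").upper()
    for res in structure.residues:
        if res.author_seq_id == seq and res.insertion_code.strip().upper() == icode:
            if name is not None and res.name != name.upper():
                raise StructureError(
                    f"CDR endpoint {endpoint!r}: residue {res.label} at author "
                    f"position {seq} is {res.name}, not {name.upper()}"
                )
            return res.index
    raise StructureError(f"CDR endpoint {endpoint!r} not found in structure")


def annotate_cdrs(structure: StructureModel, ranges: Sequence) -> StructureModel:
    """Attach CDR loop spans (author numbering) to a structure.

    ``ranges`` is a sequence of up to three ``(start, end)`` pairs, each
    endpoint an author seq id (int) or a label such as ``"Leu23"``.  Spans
    must be well-ordered and non-overlapping.  Returns a new annotated
    :class:`StructureModel` sharing the atoms.
    """
    resolved: list[tuple[int, int]] = []
    for start, end in ranges:
        s = _resolve_endpoint(structure, start)
        e = _resolve_endpoint(structure, end)
        if e < s:
            raise StructureError(f"CDR span ({start!r}, {end!r}) is reversed")
        resolved.append((s, e))
    resolved.sort()
    for (s1, e1), (s2, e2) in zip(resolved, resolved[1:]):
        if s2 <= e1:
            raise StructureError("CDR spans overlap — malformed annotation")
    return StructureModel(
        atoms=structure.atoms,
        residues=structure.residues,
        source_id=structure.source_id,
        cdr_ranges=resolved,
    )
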