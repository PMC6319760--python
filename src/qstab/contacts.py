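"""Native contact map: heavy-atom pairs of the reference structure.

A native contact is an unordered pair of heavy atoms closer than a cutoff in
the reference structure, with the two atoms in sequence-separated residues.
The defaults (4.5 A cutoff, residue separation |i-j| > 3, heavy atoms only)
follow the standard soft fraction-of-native-contacts definition; they are
configurable and echoed in every report for provenance.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .structures import ResidueGroupScheme, StructureModel

__all__ = [
    "ContactParameters",
    "NativeContactSet",
    "build_native_contacts",
    "mask_by_groups",
    "mask_by_residue",
    "excluded_residues",
    "EmptyContactSetError",
]


class EmptyContactSetError(ValueError):
    """Raised when a contact definition yields no pairs (Q undefined)."""


@dataclasses.dataclass(frozen=True)
class ContactParameters:
    """Numeric definition of a native contact.

    cutoff : Angstrom; a pair is native iff its reference distance is
        strictly below this (tie at the cutoff excluded, for determinism).
    min_residue_separation : pairs are kept only if |i - j| of the internal
        residue indices exceeds this (default 3, i.e. |delta| > 3).
    heavy_atoms_only : drop hydrogens before the search (default True).
    """

    cutoff: float = 4.5
    min_residue_separation: int = 3
    heavy_atoms_only: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_residue_separation < 0:
            raise ValueError("min_residue_separation must be >= 0")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class NativeContactSet:
    """Heavy-atom pairs defining the native contacts of one structure.

    Stores, per pair, the indices of the two atoms (into
    ``structure.atoms``), the native distance ``r0`` (Angstrom) and the two
    residue indices.  Subsets produced by the masking operations share the
    structure and parameters and carry a ``selection_label``.
    """

    def __init__(
        self,
        structure: StructureModel,
        atom_i: np.ndarray,
        atom_j: np.ndarray,
        r0: np.ndarray,
        params: ContactParameters,
        selection_label: str = "all-all",
    ) -> None:
        self.structure = structure
        self.atom_i = np.asarray(atom_i, dtype=np.intp)
        self.atom_j = np.asarray(atom_j, dtype=np.intp)
        self.r0 = np.asarray(r0, dtype=np.float64)
        self.params = params
        self.selection_label = selection_label
        self.res_i = np.array(
            [structure.atoms[k].residue_index for k in self.atom_i], dtype=np.intp
        )
        self.res_j = np.array(
            [structure.atoms[k].residue_index for k in self.atom_j], dtype=np.intp
        )

    def __len__(self) -> int:
        return int(self.atom_i.size)

    @property
    def n_pairs(self) -> int:
        return len(self)

    @property
    def pairs(self) -> list[tuple[int, int, float]]:
        """Pairs as (serial_a, serial_b, r0) tuples, for inspection."""
        atoms = self.structure.atoms
        return [
            (atoms[i].serial, atoms[j].serial, float(d))
            for i, j, d in zip(self.atom_i, self.atom_j, self.r0)
        ]

    @property
    def per_residue_counts(self) -> np.ndarray:
        """Number of contact pairs touching each residue (length n_residues)."""
        counts = np.bincount(
            np.concatenate([self.res_i, self.res_j]),
            minlength=self.structure.n_residues,
        )
        return counts

    def subset(self, mask: np.ndarray, selection_label: str) -> "NativeContactSet":
        mask = np.asarray(mask)
        return NativeContactSet(
            self.structure,
            self.atom_i[mask],
            self.atom_j[mask],
            self.r0[mask],
            self.params,
            selection_label=selection_label,
        )

    # -- masking --------------------------------------------------------
    def by_groups(
        self, scheme: ResidueGroupScheme, group_a: str, group_b: str
    ) -> "NativeContactSet":
        return mask_by_groups(self, scheme, group_a, group_b)

    def by_residue(self, residue_index: int, exclude_cap: bool = True) -> "NativeContactSet":
        return mask_by_residue(self, residue_index, exclude_cap=exclude_cap)

    # -- I/O ------------------------------------------------------------
    def to_csv(self, path) -> None:
        import pandas as pd

        atoms = self.structure.atoms
        df = pd.DataFrame(
            {
                "serial_a": [atoms[i].serial for i in self.atom_i],
                "serial_b": [atoms[j].serial for j in self.atom_j],
                "residue_a": self.res_i,
                "residue_b": self.res_j,
                "r0_angstrom": self.r0,
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(
        cls, path, structure: StructureModel, params: ContactParameters
    ) -> "NativeContactSet":
        import pandas as pd

        df = pd.read_csv(path)
        serial_to_index = {a.serial: k for k, a in enumerate(structure.atoms)}
        ai = np.array([serial_to_index[s] for s in df["serial_a"]], dtype=np.intp)
        aj = np.array([serial_to_index[s] for s in df["serial_b"]], dtype=np.intp)
        return cls(structure, ai, aj, df["r0_angstrom"].to_numpy(), params)


def build_native_contacts(
    structure: StructureModel, params: Optional[ContactParameters] = None
) -> NativeContactSet:
    """Build the native contact set of a reference structure.

    Deterministic: pairs are sorted by (serial_a, serial_b) with
    serial_a < serial_b; native distances are stored to full precision.
    Raises :class:`EmptyContactSetError` if no pair qualifies.
    """
    params = params or ContactParameters()
    if params.heavy_atoms_only:
        atom_idx = structure.heavy_atom_indices()
    else:
        atom_idx = np.arange(structure.n_atoms, dtype=np.intp)
    if atom_idx.size < 2:
        raise EmptyContactSetError("fewer than two atoms selected")

    coords = structure.coords[atom_idx]
    res_of = np.array(
        [structure.atoms[k].residue_index for k in atom_idx], dtype=np.intp
    )

    tree = cKDTree(coords)
    cand = tree.query_pairs(r=params.cutoff, output_type="ndarray")
    if cand.size == 0:
        raise EmptyContactSetError("no atom pair within the cutoff")
    d = np.linalg.norm(coords[cand[:, 0]] - coords[cand[:, 1]], axis=1)
    sep = np.abs(res_of[cand[:, 0]] - res_of[cand[:, 1]])
    keep = (d < params.cutoff) & (sep > params.min_residue_separation)
    cand, d = cand[keep], d[keep]
    if cand.size == 0:
        raise EmptyContactSetError(
            "no native contacts under the given cutoff/separation rules"
        )

    ai = atom_idx[cand[:, 0]]
    aj = atom_idx[cand[:, 1]]
    # canonical order: serial_a < serial_b, then sort pair list
    serials = np.array([a.serial for a in structure.atoms])
    swap = serials[ai] > serials[aj]
    ai[swap], aj[swap] = aj[swap], ai[swap].copy()
    order = np.lexsort((serials[aj], serials[ai]))
    return NativeContactSet(structure, ai[order], aj[order], d[order], params)


def mask_by_groups(
    contacts: NativeContactSet,
    scheme: ResidueGroupScheme,
    group_a: str,
    group_b: str,
) -> NativeContactSet:
    """Select pairs between two physicochemical groups (unordered match).

    A pair is kept iff one member's residue is in ``group_a`` and the other's
    in ``group_b``; ``"all"`` acts as a wildcard, so ``("all", "all")``
    returns the full set.  The returned subset may be empty; callers that
    need a defined Q must check.
    """
    for g in (group_a, group_b):
        if g != "all" and g not in scheme.GROUPS:
            raise ValueError(f"unknown residue group {g!r}")
    label = f"{group_a}-{group_b}"
    if group_a == "all" and group_b == "all":
        return contacts.subset(np.ones(len(contacts), dtype=bool), label)

    names = contacts.structure.residue_names()
    group_of = np.array([scheme.classify(n) for n in names])
    gi = group_of[contacts.res_i]
    gj = group_of[contacts.res_j]
    if group_a == "all" or group_b == "all":
        g = group_b if group_a == "all" else group_a
        mask = (gi == g) | (gj == g)
    else:
        mask = ((gi == group_a) & (gj == group_b)) | (
            (gi == group_b) & (gj == group_a)
        )
    return contacts.subset(mask, label)


def mask_by_residue(
    contacts: NativeContactSet, residue_index: int, exclude_cap: bool = True
) -> NativeContactSet:
    """All pairs with at least one atom in the given residue.

    With ``exclude_cap`` (default), pairs that touch the residue only through
    a terminal capping-group atom are left out of the per-residue selection.
    """
    if not (0 <= residue_index < contacts.structure.n_residues):
        raise IndexError(f"residue index {residue_index} out of range")
    atoms = contacts.structure.atoms
    if exclude_cap:
        touch_i = (contacts.res_i == residue_index) & np.array(
            [not atoms[k].is_cap for k in contacts.atom_i]
        )
        touch_j = (contacts.res_j == residue_index) & np.array(
            [not atoms[k].is_cap for k in contacts.atom_j]
        )
        mask = touch_i | touch_j
    else:
        mask = (contacts.res_i == residue_index) | (contacts.res_j == residue_index)
    label = f"residue:{contacts.structure.residue_label(residue_index)}"
    return contacts.subset(mask, label)


def excluded_residues(contacts: NativeContactSet, min_contacts: int = 30) -> list[int]:
    """Residues with fewer than ``min_contacts`` native contacts.

    Such residues have too few pairs for a reliable per-residue Q and are
    reported separately, never flagged as unstable.  Strict inequality:
    29 contacts excludes, 30 does not.
    """
    counts = contacts.per_residue_counts
    return [int(i) for i in np.nonzero(counts < min_contacts)[0]]
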