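"""Soft fraction-of-native-contacts (Q).

For a frame with pair distances :math:`r_{ij}` and a native contact set with
reference distances :math:`r^0_{ij}`,

.. math::

    Q = \\frac{1}{N} \\sum_{(i,j)} \\frac{1}{1 + \\exp[\\beta (r_{ij} - \\lambda r^0_{ij})]}

with smoothing :math:`\\beta` (default 5 A^-1) and tolerance factor
:math:`\\lambda` (default 1.8).  Each pair contributes a value in (0, 1) that
decreases smoothly as the pair separates beyond :math:`\\lambda r^0`; the
logistic is evaluated in a numerically safe form so arbitrarily unfolded
frames cause no overflow.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.special import expit

from .contacts import NativeContactSet
from .series import QTimeSeries
from .structures import ResidueGroupScheme

__all__ = [
    "QParameters",
    "Frame",
    "QTimeSeries",
    "soft_q",
    "contact_contributions",
    "q_timeseries",
    "group_pair_q_series",
    "per_residue_q_series",
    "UndefinedQError",
]


class UndefinedQError(ValueError):
    """Raised when Q is requested over an empty contact selection."""


@dataclasses.dataclass(frozen=True)
class QParameters:
    """Smoothing beta (A^-1, > 0) and tolerance factor lambda (>= 1)."""

    beta: float = 5.0
    lam: float = 1.8

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.lam < 1:
            raise ValueError("lam must be >= 1")

    def as_dict(self) -> dict:
        return {"beta": self.beta, "lam": self.lam}


@dataclasses.dataclass
class Frame:
    """A single coordinate frame conforming to the reference atom ordering."""

    xyz: np.ndarray  # (n_atoms, 3), Angstrom
    time: float = 0.0  # ns
    replica_id: int = 0


def _check_selection(contacts: NativeContactSet) -> None:
    if len(contacts) == 0:
        raise UndefinedQError(
            f"Q is undefined over the empty selection {contacts.selection_label!r}"
        )


def _pair_distances(xyz: np.ndarray, contacts: NativeContactSet) -> np.ndarray:
    diff = xyz[..., contacts.atom_i, :] - xyz[..., contacts.atom_j, :]
    return np.sqrt(np.einsum("...k,...k->...", diff, diff))


def soft_q(frame, contacts: NativeContactSet, params: Optional[QParameters] = None) -> float:
    """Q of one frame over a contact selection.

    ``frame`` may be a :class:`Frame` or a bare (n_atoms, 3) array in
    Angstrom.  Deterministic; Q lies strictly inside (0, 1).
    """
    params = params or QParameters()
    _check_selection(contacts)
    xyz = frame.xyz if isinstance(frame, Frame) else np.asarray(frame, dtype=np.float64)
    if xyz.shape != (contacts.structure.n_atoms, 3):
        raise ValueError(
            f"frame has shape {xyz.shape}, reference expects "
            f"({contacts.structure.n_atoms}, 3)"
        )
    r = _pair_distances(xyz, contacts)
    # expit(-x) == 1/(1+exp(x)) evaluated without overflow
    return float(np.mean(expit(-params.beta * (r - params.lam * contacts.r0))))


def contact_contributions(
    xyz_frames: np.ndarray,
    contacts: NativeContactSet,
    params: Optional[QParameters] = None,
) -> np.ndarray:
    """Per-pair logistic contributions, shape (n_frames, n_pairs).

    The Q of any column subset is the row mean over those columns; the
    analysis pipeline computes this matrix once per replica and derives all
    group-pair and per-residue series from it.
    """
    params = params or QParameters()
    _check_selection(contacts)
    xyz_frames = np.asarray(xyz_frames, dtype=np.float64)
    r = _pair_distances(xyz_frames, contacts)
    return expit(-params.beta * (r - params.lam * contacts.r0))


def q_timeseries(
    replica,
    contacts: NativeContactSet,
    params: Optional[QParameters] = None,
    chunk_frames: int = 256,
) -> QTimeSeries:
    """Q per frame along one replica, order-preserving.

    Frames are processed in chunks so memory stays bounded in the number of
    frames regardless of trajectory length.
    """
    params = params or QParameters()
    _check_selection(contacts)
    xyz = np.asarray(replica.xyz, dtype=np.float64)
    if xyz.ndim != 3 or xyz.shape[1:] != (contacts.structure.n_atoms, 3):
        raise ValueError(
            f"replica frames have shape {xyz.shape[1:]}, reference expects "
            f"({contacts.structure.n_atoms}, 3)"
        )
    values = np.empty(xyz.shape[0], dtype=np.float64)
    for start in range(0, xyz.shape[0], chunk_frames):
        block = xyz[start : start + chunk_frames]
        values[start : start + block.shape[0]] = contact_contributions(
            block, contacts, params
        ).mean(axis=1)
    return QTimeSeries(
        times=np.asarray(replica.times, dtype=np.float64),
        values=values,
        selection_label=contacts.selection_label,
        replica_id=getattr(replica, "replica_id", 0),
    )


def group_pair_q_series(
    replica,
    contacts: NativeContactSet,
    scheme: ResidueGroupScheme,
    group_a: str,
    group_b: str,
    params: Optional[QParameters] = None,
) -> QTimeSeries:
    """Q series restricted to contacts between two residue groups.

    Raises :class:`UndefinedQError` when the group pair selects no contact;
    downstream averaging treats such selections as undefined and logs them.
    """
    subset = contacts.by_groups(scheme, group_a, group_b)
    if len(subset) == 0:
        raise UndefinedQError(
            f"group pair ({group_a}, {group_b}) selects no native contact"
        )
    return q_timeseries(replica, subset, params)


def per_residue_q_series(
    replica,
    contacts: NativeContactSet,
    residue_index: int,
    params: Optional[QParameters] = None,
) -> QTimeSeries:
    """Q of one residue against all its native-contact partners."""
    subset = contacts.by_residue(residue_index)
    if len(subset) == 0:
        raise UndefinedQError(
            f"residue {contacts.structure.residue_label(residue_index)} has no "
            "native contacts; its Q is undefined"
        )
    return q_timeseries(replica, subset, params)
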