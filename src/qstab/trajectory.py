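"""Trajectory ensembles, backbone RMSD and final-window averaging.

An ensemble holds one or more replicas of the same system — independent
trajectories differing only in their random initial conditions.  Frames
always conform to the reference structure's atom ordering and are stored in
Angstrom; readers that natively report nm (the mdtraj-backed binary formats)
convert on read, logged once.

Averages follow the final-window rule: per replica, only frames in the last
``window_fraction`` of that replica's own time span enter the statistics
(default 0.3, i.e. the final 30 ns of a 100 ns run).  The headline mean and
SD pool the selected frames across all replicas, which captures both intra-
and inter-replica spread; per-replica means are retained for alternative
summaries.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .series import TimeSeries, QTimeSeries
from .structures import StructureModel, StructureError

__all__ = [
    "Replica",
    "TrajectoryEnsemble",
    "TimeSeries",
    "WindowStats",
    "load_trajectory",
    "superpose",
    "backbone_rmsd_series",
    "final_window_stats",
]

logger = logging.getLogger(__name__)
_NM_WARNED = False

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclasses.dataclass
class Replica:
    """Ordered coordinate frames of one trajectory replica (Angstrom, ns)."""

    replica_id: int
    times: np.ndarray  # (n_frames,), ns, strictly increasing
    xyz: np.ndarray  # (n_frames, n_atoms, 3), Angstrom

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_atoms, 3)")
        if self.times.shape[0] != self.xyz.shape[0]:
            raise ValueError("times and xyz disagree on frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.xyz.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.xyz.shape[1])


@dataclasses.dataclass
class TrajectoryEnsemble:
    """Replica trajectories of one system, tied to a reference structure."""

    system_id: str
    reference: StructureModel
    replicas: list

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValueError("an ensemble needs at least one replica")
        for rep in self.replicas:
            if rep.n_atoms != self.reference.n_atoms:
                raise ValueError(
                    f"replica {rep.replica_id} has {rep.n_atoms} atoms, "
                    f"reference has {self.reference.n_atoms}"
                )

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)


def load_trajectory(
    path,
    reference: StructureModel,
    replica_id: int = 0,
    dt_ns: Optional[float] = None,
    topology_path=None,
) -> Replica:
    """Read one trajectory replica conforming to the reference atom order.

    Multi-model PDB is always supported; ``.xtc``/``.dcd``/``.trr`` are read
    through mdtraj when it is installed (coordinates converted nm -> A).
    Frame times come from ``dt_ns`` (frame k at ``(k+1)*dt_ns``) or, for
    binary formats, from the file's own time stamps when present.
    """
    global _NM_WARNED
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        xyz = _read_multimodel_pdb(path, reference)
        times = None
    elif suffix in (".xtc", ".dcd", ".trr", ".nc", ".h5"):
        try:
            import mdtraj
        except ImportError as exc:
            raise StructureError(
                f"reading {suffix} trajectories requires mdtraj"
            ) from exc
        top = str(topology_path) if topology_path else None
        if top is None:
            raise StructureError(
                "binary trajectory formats need topology_path (the reference PDB)"
            )
        traj = mdtraj.load(str(path), top=top)
        if traj.n_atoms != reference.n_atoms:
            raise StructureError(
                f"{path}: {traj.n_atoms} atoms, reference has {reference.n_atoms}"
            )
        if not _NM_WARNED:
            logger.info("converting mdtraj coordinates from nm to Angstrom")
            _NM_WARNED = True
        xyz = np.asarray(traj.xyz, dtype=np.float64) * 10.0  # nm -> A
        times = np.asarray(traj.time, dtype=np.float64) / 1000.0  # ps -> ns
        if times.size and np.any(np.diff(times) <= 0):
            times = None
    else:
        raise StructureError(f"unsupported trajectory format {suffix!r}")

    n_frames = xyz.shape[0]
    if times is None:
        step = dt_ns if dt_ns is not None else 1.0
        times = step * np.arange(1, n_frames + 1, dtype=np.float64)
    return Replica(replica_id=replica_id, times=times, xyz=xyz)


def _read_multimodel_pdb(path: Path, reference: StructureModel) -> np.ndarray:
    """Coordinate frames from MODEL/ENDMDL blocks, in file atom order."""
    frames: list[np.ndarray] = []
    current: list[list[float]] = []
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                current = []
            elif rec == "ENDMDL":
                frames.append(np.array(current, dtype=np.float64))
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
    if not frames:
        if not current:
            raise StructureError(f"{path} contains no coordinate frames")
        frames.append(np.array(current, dtype=np.float64))  # single MODEL-less file
    xyz = np.stack(frames)
    if xyz.shape[1] != reference.n_atoms:
        raise StructureError(
            f"{path}: frames have {xyz.shape[1]} atoms, reference has "
            f"{reference.n_atoms}"
        )
    return xyz


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of ``mobile`` onto ``target``.

    Returns the transformed mobile coordinates and the RMSD (same units as
    input).  The rotation is proper (determinant +1); reflections are
    corrected via the sign of the smallest singular value.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("superpose expects two (n, 3) arrays of equal shape")
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    x = mobile - mu_m
    y = target - mu_t
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    moved = x @ rot + mu_t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return moved, rmsd


def _backbone_indices(reference: StructureModel, names=BACKBONE_NAMES) -> np.ndarray:
    idx = [
        i
        for i, a in enumerate(reference.atoms)
        if a.name.strip() in names and not a.is_hydrogen and not a.is_cap
    ]
    if not idx:
        raise StructureError(
            f"reference has no backbone atoms named {names}"
        )
    return np.array(idx, dtype=np.intp)


def backbone_rmsd_series(
    replica: Replica,
    reference: StructureModel,
    backbone_names: Sequence[str] = BACKBONE_NAMES,
) -> TimeSeries:
    """Backbone RMSD vs the reference per frame, after optimal superposition.

    Backbone = N, C-alpha, C, O by default (carbonyl O included,
    configurable).  Values are reported in nm to match the field's plotting
    convention, although internal coordinates are Angstrom.
    """
    idx = _backbone_indices(reference, tuple(backbone_names))
    target = reference.coords[idx]
    values = np.empty(replica.n_frames, dtype=np.float64)
    for k in range(replica.n_frames):
        _, rmsd_angstrom = superpose(replica.xyz[k][idx], target)
        values[k] = rmsd_angstrom / 10.0  # A -> nm
    return TimeSeries(
        times=replica.times,
        values=values,
        selection_label="rmsd_backbone",
        replica_id=replica.replica_id,
        units="nm",
    )


# ---------------------------------------------------------------------------
# Final-window statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class WindowStats:
    """Final-window summary of one observable across replicas.

    ``mean``/``sd`` pool all selected frames across replicas (population SD);
    ``per_replica_means`` holds each replica's own window mean, aligned with
    ``replica_ids``.
    """

    mean: float
    sd: float
    n_frames: int
    window: tuple
    per_replica_means: list
    replica_ids: list

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("window selected no frames")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "n_frames": self.n_frames,
            "window": list(self.window),
            "per_replica_means": list(self.per_replica_means),
            "replica_ids": list(self.replica_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WindowStats":
        return cls(
            mean=d["mean"],
            sd=d["sd"],
            n_frames=d["n_frames"],
            window=tuple(d["window"]),
            per_replica_means=list(d["per_replica_means"]),
            replica_ids=list(d["replica_ids"]),
        )


def final_window_stats(
    series: Union[TimeSeries, Sequence[TimeSeries]],
    window_fraction: float = 0.3,
    window_ns: Optional[float] = None,
) -> WindowStats:
    """Average an observable over the final window of each replica.

    Per replica, frames with ``t >= (1 - window_fraction) * t_end`` are
    selected (``t_end`` the replica's own last time); with ``window_ns`` the
    absolute rule ``t >= t_end - window_ns`` is used instead.  The ensemble
    mean/SD pool the selected frames of all replicas.
    """
    if isinstance(series, TimeSeries):
        series = [series]
    if not series:
        raise ValueError("no series given")
    if window_ns is None and not (0 < window_fraction <= 1):
        raise ValueError("window_fraction must be in (0, 1]")

    pooled: list[np.ndarray] = []
    per_replica_means: list[float] = []
    replica_ids: list[int] = []
    t_starts, t_ends = [], []
    for s in series:
        t_end = float(s.times[-1])
        t_start = t_end - window_ns if window_ns is not None else (1.0 - window_fraction) * t_end
        sel = s.times >= t_start - 1e-12
        if not np.any(sel):
            raise ValueError(
                f"window [{t_start}, {t_end}] selects no frames for replica "
                f"{s.replica_id}"
            )
        pooled.append(s.values[sel])
        per_replica_means.append(float(np.mean(s.values[sel])))
        replica_ids.append(s.replica_id)
        t_starts.append(t_start)
        t_ends.append(t_end)

    allv = np.concatenate(pooled)
    return WindowStats(
        mean=float(np.mean(allv)),
        sd=float(np.std(allv)),
        n_frames=int(allv.size),
        window=(float(min(t_starts)), float(max(t_ends))),
        per_replica_means=per_replica_means,
        replica_ids=replica_ids,
    )
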