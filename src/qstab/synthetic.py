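"""Synthetic reference structures and replica ensembles with designed instability.

The generator emulates the phenomenology the analysis stages must detect in
real unfolding trajectories of immunoglobulin-fold domains: a mostly stable
framework, a minority of residues that lose their native contacts partway
through the run, replica-to-replica variation from random seeds, and
(optionally) rigid-body drift that superposition must remove.  Unfolding is
displacement-based — each designed-unstable residue is carried away
coherently along a random per-replica direction once its onset time has
passed — which gives exact control over which residues lose contacts and
when.  No force field or integrator is involved; physically realistic
kinetics are a non-goal.

The toy fold is a compact two-sheet sandwich: residues are laid out on
serpentine strands in two stacked layers, each residue carrying a small
cluster of heavy atoms, so that default contact parameters give core
residues well over 30 native contacts while chain termini fall below the
reliability threshold (exercising the exclusion rule).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .structures import Atom, Residue, StructureModel, STANDARD_RESIDUES
from .trajectory import Replica, TrajectoryEnsemble

__all__ = [
    "InstabilityProfile",
    "SyntheticSystemSpec",
    "make_toy_structure",
    "simulate_ensemble",
    "build_system",
    "make_benchmark_suite",
]

# Per-residue heavy-atom offset pattern (Angstrom) relative to the residue
# centre; truncated/extended to atoms_per_residue.
_ATOM_TEMPLATE = (
    ("N", (-1.2, -0.9, 0.5)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C", (1.2, -0.8, -0.4)),
    ("O", (1.7, -2.1, 0.2)),
    ("CB", (0.3, 1.3, 1.2)),
    ("CG", (-0.5, 2.3, 2.2)),
    ("CD", (1.3, 2.6, 0.4)),
    ("CE", (-1.5, 1.7, -1.4)),
)

# Deterministic residue-name cycle mixing the three physicochemical groups.
_NAME_CYCLE = (
    "ALA", "ASP", "PHE", "GLY", "GLU", "TYR", "SER", "GLN", "TRP", "THR",
    "ASN", "LEU", "ARG", "VAL", "LYS", "ILE", "HIS", "MET", "CYS", "PRO",
)


@dataclasses.dataclass
class InstabilityProfile:
    """Designed per-residue instability of a synthetic ensemble.

    amplitudes : per-residue terminal displacement scale s_i (Angstrom);
        0 keeps the residue native up to thermal jitter.
    onsets : per-residue onset fraction tau_i in [0, 1] — the point in the
        run at which residue i begins to lose contacts.
    base_noise : global thermal jitter sigma0 (Angstrom) applied i.i.d. to
        every atom of every frame.
    rigid_body : superimpose a smoothly growing random rigid rotation and
        translation on every frame (removed by superposition, visible in
        raw coordinates).
    """

    amplitudes: np.ndarray
    onsets: np.ndarray
    base_noise: float = 0.25
    rigid_body: bool = False

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        self.onsets = np.asarray(self.onsets, dtype=np.float64)
        if self.amplitudes.shape != self.onsets.shape:
            raise ValueError("amplitudes and onsets must align")
        if np.any(~np.isfinite(self.amplitudes)) or np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be finite and >= 0")
        if np.any((self.onsets < 0) | (self.onsets > 1)):
            raise ValueError("onsets must lie in [0, 1]")
        if self.base_noise < 0:
            raise ValueError("base_noise must be >= 0")

    @classmethod
    def stable(cls, n_residues: int, base_noise: float = 0.25,
               rigid_body: bool = False) -> "InstabilityProfile":
        return cls(
            amplitudes=np.zeros(n_residues),
            onsets=np.ones(n_residues),
            base_noise=base_noise,
            rigid_body=rigid_body,
        )

    @classmethod
    def with_unstable(
        cls,
        n_residues: int,
        unstable: dict,
        base_noise: float = 0.25,
        rigid_body: bool = False,
    ) -> "InstabilityProfile":
        """Profile with ``unstable`` = {residue_index: (amplitude, onset)}."""
        prof = cls.stable(n_residues, base_noise=base_noise, rigid_body=rigid_body)
        for idx, (amp, onset) in unstable.items():
            prof.amplitudes[idx] = amp
            prof.onsets[idx] = onset
        return prof


@dataclasses.dataclass
class SyntheticSystemSpec:
    """Full recipe for one synthetic system (structure + ensemble).

    Defaults mirror the study design the analysis targets: ten replicas per
    system, frames saved on a uniform grid spanning a 100 ns run (200 frames
    at 0.5 ns — the real 10 ps save interval scaled down), and a 60-residue
    two-sheet fold.
    """

    system_id: str = "toy"
    n_residues: int = 60
    atoms_per_residue: int = 5
    strand_length: int = 10
    strands_per_sheet: int = 3
    profile: Optional[InstabilityProfile] = None
    n_replicas: int = 10
    n_frames: int = 200
    dt_ns: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ValueError("n_residues must be >= 10")
        if not (2 <= self.atoms_per_residue <= len(_ATOM_TEMPLATE)):
            raise ValueError(
                f"atoms_per_residue must be in [2, {len(_ATOM_TEMPLATE)}]"
            )
        if self.n_replicas < 1 or self.n_frames < 2 or self.dt_ns <= 0:
            raise ValueError("invalid ensemble dimensions")
        if self.profile is None:
            self.profile = InstabilityProfile.stable(self.n_residues)
        if self.profile.amplitudes.shape[0] != self.n_residues:
            raise ValueError("profile length must equal n_residues")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["profile"] = {
            "amplitudes": self.profile.amplitudes.tolist(),
            "onsets": self.profile.onsets.tolist(),
            "base_noise": self.profile.base_noise,
            "rigid_body": self.profile.rigid_body,
        }
        return d


# ---------------------------------------------------------------------------
# Structure generation
# ---------------------------------------------------------------------------

# Lattice constants (Angstrom): spacing along a strand, between strands in a
# sheet, and between the two sheets.  Chosen so adjacent-strand and
# cross-sheet atom pairs fall inside the default 4.5 A contact cutoff.
_STRAND_STEP = 3.2
_ROW_STEP = 3.8
_SHEET_STEP = 4.0
_TERMINAL_EXTENSION = 3.2  # A, chain termini dangle radially outward
_JITTER = 0.06  # A, static heterogeneity of atom placement
_MIN_DISTANCE = 1.0  # A, steric floor
_MAX_RETRIES = 8


def _residue_centres(spec: SyntheticSystemSpec) -> np.ndarray:
    L = spec.strand_length
    per_sheet = spec.strands_per_sheet
    centres = np.empty((spec.n_residues, 3))
    for i in range(spec.n_residues):
        strand, pos = divmod(i, L)
        sheet, row = divmod(strand, per_sheet)
        if strand % 2 == 1:  # serpentine: alternate strand direction
            pos = L - 1 - pos
        if sheet % 2 == 1:  # fold back the row order in alternate sheets
            row = per_sheet - 1 - row
        centres[i] = (
            _STRAND_STEP * pos,
            _ROW_STEP * row,
            _SHEET_STEP * sheet,
        )
    # chain termini dangle away from the core, as real termini do; this also
    # guarantees low-contact residues for the exclusion rule to act on
    centroid = centres.mean(axis=0)
    for i in (0, spec.n_residues - 1):
        v = centres[i] - centroid
        centres[i] += _TERMINAL_EXTENSION * v / np.linalg.norm(v)
    return centres


def make_toy_structure(spec: SyntheticSystemSpec) -> StructureModel:
    """Deterministic compact toy fold for a given spec (and its seed).

    Raises if the placement cannot satisfy the 1.0 A steric floor within a
    bounded number of jitter retries.
    """
    centres = _residue_centres(spec)
    template = _ATOM_TEMPLATE[: spec.atoms_per_residue]
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 11, attempt])
        )
        coords = np.empty((spec.n_residues * len(template), 3))
        k = 0
        for i in range(spec.n_residues):
            for _, offset in template:
                coords[k] = centres[i] + np.asarray(offset) + _JITTER * rng.standard_normal(3)
                k += 1
        if _min_pair_distance(coords) >= _MIN_DISTANCE:
            break
    else:
        raise RuntimeError(
            "toy-structure placement collided sterically in every retry"
        )

    atoms: list[Atom] = []
    residues: list[Residue] = []
    serial = 0
    k = 0
    for i in range(spec.n_residues):
        name = _NAME_CYCLE[i % len(_NAME_CYCLE)]
        residues.append(Residue(i, name, i + 1, " ", "A"))
        for atom_name, _ in template:
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name=atom_name,
                    element=atom_name[0],
                    residue_index=i,
                    residue_name=name,
                    chain_id="A",
                    xyz=coords[k].copy(),
                )
            )
            k += 1
    return StructureModel(atoms, residues, source_id=spec.system_id)


def _min_pair_distance(coords: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    return float(d[:, 1].min())


# ---------------------------------------------------------------------------
# Ensemble simulation
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    ux, uy, uz = axis
    c, s = np.cos(angle), np.sin(angle)
    return np.array(
        [
            [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
        ]
    )


def simulate_ensemble(
    structure: StructureModel, spec: SyntheticSystemSpec
) -> TrajectoryEnsemble:
    """Generate the replica ensemble for a structure under a spec's profile.

    Frame k (time ``(k+1)*dt_ns``) is the native structure plus i.i.d.
    thermal jitter, plus — for every residue whose onset has passed — a
    coherent displacement of all its atoms that grows smoothly (smoothstep
    in the elapsed fraction past onset) up to the residue's amplitude, along
    a direction drawn once per (residue, replica).  Optional rigid-body
    drift applies a growing random rotation about the centroid and a
    translation to the whole frame.  Replicas differ only through
    per-replica substreams of the master seed, so identical spec + seed
    reproduce the ensemble bitwise.
    """
    profile = spec.profile
    n_atoms = structure.n_atoms
    native = structure.coords
    res_index = np.array([a.residue_index for a in structure.atoms], dtype=np.intp)
    times = spec.dt_ns * np.arange(1, spec.n_frames + 1)
    t_end = times[-1]
    frac = times / t_end

    master = np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 23])
    children = master.spawn(spec.n_replicas)

    # growth(t, i): smoothstep of elapsed fraction past the residue's onset
    denom = np.maximum(1.0 - profile.onsets, 1e-9)
    growth = _smoothstep(
        (frac[:, None] - profile.onsets[None, :]) / denom[None, :]
    )  # (n_frames, n_residues)
    growth = growth * profile.amplitudes[None, :]

    centroid = native.mean(axis=0)
    replicas = []
    for rep_id, child in enumerate(children):
        rng = np.random.default_rng(child)
        directions = rng.standard_normal((structure.n_residues, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        xyz = np.repeat(native[None, :, :], spec.n_frames, axis=0)
        # coherent per-residue escape displacement
        xyz += (growth[:, res_index, None] * directions[res_index][None, :, :])
        if profile.base_noise > 0:
            xyz += profile.base_noise * rng.standard_normal(xyz.shape)
        if profile.rigid_body:
            axis = rng.standard_normal(3)
            total_angle = rng.uniform(0.5, 1.5)  # rad, reached at t_end
            total_shift = rng.normal(0.0, 8.0, size=3)  # A
            for k in range(spec.n_frames):
                rot = _rotation_matrix(axis, total_angle * frac[k])
                xyz[k] = (xyz[k] - centroid) @ rot.T + centroid + total_shift * frac[k]
        replicas.append(Replica(replica_id=rep_id, times=times.copy(), xyz=xyz))

    return TrajectoryEnsemble(
        system_id=spec.system_id, reference=structure, replicas=replicas
    )


def build_system(spec: SyntheticSystemSpec) -> tuple[StructureModel, TrajectoryEnsemble]:
    """Convenience: toy structure plus its simulated ensemble."""
    structure = make_toy_structure(spec)
    return structure, simulate_ensemble(structure, spec)


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------

# Benchmark design constants: a designed-unstable residue is displaced by
# 12 A (enough to break all its native contacts at full growth), the number
# of such residues scales with the instability level, and onsets shift later
# for more stable systems (stable folds start dropping late in the run).
_BENCH_AMPLITUDE = 12.0
_BENCH_MAX_UNSTABLE = 12
_PSEUDO_TM_RANGE = (47.0, 85.0)


def make_benchmark_suite(
    n_systems: int = 7,
    gradient: Optional[Sequence[float]] = None,
    seed: int = 0,
    n_residues: int = 60,
    n_replicas: int = 10,
    n_frames: int = 200,
    dt_ns: float = 0.5,
) -> list[tuple[SyntheticSystemSpec, float]]:
    """Specs for a multi-system benchmark with a monotone stability gradient.

    ``gradient`` gives each system's designed instability level (default a
    strictly decreasing ramp from 1 to 0); pseudo melting temperatures are
    assigned on an increasing grid spanning roughly 47-85 degC, so designed
    instability decreases as pseudo-Tm increases.  Reversing the gradient
    reverses that relationship (and flips the sign of any Q-vs-Tm
    correlation downstream).
    """
    if gradient is None:
        gradient = np.linspace(1.0, 0.0, n_systems)
    gradient = np.asarray(gradient, dtype=np.float64)
    if gradient.shape[0] != n_systems:
        raise ValueError("gradient length must equal n_systems")
    diffs = np.diff(gradient)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("gradient must be strictly monotone")

    pseudo_tm = np.linspace(*_PSEUDO_TM_RANGE, n_systems)
    suite = []
    for j, level in enumerate(gradient):
        child_seed = int(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 37, j]).generate_state(1)[0]
            % (2**31)
        )
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 41, j])
        )
        n_unstable = int(round(_BENCH_MAX_UNSTABLE * float(level)))
        candidates = np.arange(2, n_residues - 2)
        chosen = rng.choice(candidates, size=n_unstable, replace=False) if n_unstable else []
        onset = 0.3 + 0.5 * (1.0 - float(level))  # more stable -> later drop
        profile = InstabilityProfile.with_unstable(
            n_residues,
            {int(i): (_BENCH_AMPLITUDE, onset) for i in chosen},
        )
        spec = SyntheticSystemSpec(
            system_id=f"bench{j:02d}",
            n_residues=n_residues,
            profile=profile,
            n_replicas=n_replicas,
            n_frames=n_frames,
            dt_ns=dt_ns,
            seed=child_seed,
        )
        suite.append((spec, float(pseudo_tm[j])))
    return suite
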