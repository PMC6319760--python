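"""Stability decision rules and cross-system statistics.

This module applies the protocol's decision layer on top of the Q machinery:

* a residue is *unstable* in a replica if its per-residue Q averaged over the
  final window falls strictly below 0.6;
* residues with fewer than 30 native contacts have unreliable per-residue Q
  and are *excluded* — listed separately, never flagged;
* compositions of the flagged set are reported per physicochemical group,
  weighted by the number of trajectories affected per residue;
* per-system final-window Q means are correlated (Pearson) with experimental
  melting temperatures;
* wild-type and mutant reports computed under identical parameters are
  compared side by side.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .contacts import NativeContactSet, excluded_residues as _excluded_residues
from .structures import ResidueGroupScheme, StructureModel
from .trajectory import WindowStats

__all__ = [
    "TmRecord",
    "UnstableResidueRecord",
    "StabilityReport",
    "detect_unstable_residues",
    "composition_stats",
    "group_stability_fraction",
    "pearson_r",
    "correlation_table",
    "compare_variants",
    "ParameterMismatchError",
]

logger = logging.getLogger(__name__)

# The selection labels every full report carries: the plain average, each
# group against everything, and the six disjoint group pairs.
GROUPS = ("hydrophilic", "hydrophobic", "small")
GROUP_VS_ALL = tuple(f"{g}-all" for g in GROUPS)
DISJOINT_PAIRS = (
    "hydrophilic-hydrophilic",
    "hydrophilic-hydrophobic",
    "hydrophilic-small",
    "hydrophobic-hydrophobic",
    "hydrophobic-small",
    "small-small",
)
ALL_SELECTIONS = ("all-all",) + GROUP_VS_ALL + DISJOINT_PAIRS


class ParameterMismatchError(ValueError):
    """Raised when reports computed under different parameters are compared."""


@dataclasses.dataclass(frozen=True)
class TmRecord:
    """Experimental melting temperature of one system."""

    system_id: str
    tm_celsius: float


@dataclasses.dataclass(frozen=True)
class UnstableResidueRecord:
    """One (residue, replica) pair whose final-window per-residue Q fell
    below the instability threshold."""

    residue_index: int
    residue_label: str  # author numbering, e.g. "Trp47"
    residue_name: str
    replica_id: int
    mean_q_final_window: float
    in_cdr: bool
    excluded: bool = False


def detect_unstable_residues(
    per_residue_window_stats: Mapping[int, WindowStats],
    contacts: NativeContactSet,
    q_threshold: float = 0.6,
    min_contacts: int = 30,
) -> tuple[list[UnstableResidueRecord], list[int]]:
    """Flag (residue, replica) pairs with final-window per-residue Q below
    ``q_threshold`` (strict), skipping low-contact residues.

    Parameters
    ----------
    per_residue_window_stats : residue_index -> :class:`WindowStats` whose
        ``per_replica_means`` carry the replica-wise final-window means.
    contacts : the full native contact set (for per-residue contact counts).
    q_threshold : strict upper bound; a mean of exactly 0.6 is not flagged.
    min_contacts : residues with strictly fewer native contacts are
        *excluded* — returned in the second element, never flagged.

    Returns
    -------
    (records, excluded) : flagged records sorted by (residue, replica), and
        the sorted residue indices of the exclusion set.
    """
    structure = contacts.structure
    excluded = _excluded_residues(contacts, min_contacts=min_contacts)
    excluded_set = set(excluded)
    records: list[UnstableResidueRecord] = []
    for res_index in sorted(per_residue_window_stats):
        if res_index in excluded_set:
            continue
        ws = per_residue_window_stats[res_index]
        for rep_id, mean_q in zip(ws.replica_ids, ws.per_replica_means):
            if mean_q < q_threshold:
                records.append(
                    UnstableResidueRecord(
                        residue_index=res_index,
                        residue_label=structure.residue_label(res_index),
                        residue_name=structure.residues[res_index].name,
                        replica_id=rep_id,
                        mean_q_final_window=float(mean_q),
                        in_cdr=structure.in_cdr(res_index),
                    )
                )
    return records, excluded


def trajectories_affected(records: Sequence[UnstableResidueRecord]) -> dict:
    """residue_index -> number of replicas in which the residue was flagged."""
    counts: dict[int, int] = {}
    for rec in records:
        counts[rec.residue_index] = counts.get(rec.residue_index, 0) + 1
    return counts


def composition_stats(
    records: Sequence[UnstableResidueRecord],
    scheme: ResidueGroupScheme,
) -> Optional[dict]:
    """Percentage of instability attributed to each residue group.

    Each flagged residue is weighted by the number of trajectories affected;
    the three percentages sum to 100.  Returns ``None`` (undefined) when no
    residue is flagged.
    """
    if not records:
        return None
    weights: dict[str, float] = {g: 0.0 for g in scheme.GROUPS}
    by_residue = {}
    for rec in records:
        by_residue.setdefault(rec.residue_index, [rec.residue_name, 0])[1] += 1
    total = 0.0
    for res_name, n_traj in by_residue.values():
        weights[scheme.classify(res_name)] += n_traj
        total += n_traj
    return {g: 100.0 * w / total for g, w in weights.items()}


def group_stability_fraction(
    records: Sequence[UnstableResidueRecord],
    contacts: NativeContactSet,
    scheme: ResidueGroupScheme,
    group: str,
    n_replicas: int,
    min_contacts: int = 30,
) -> float:
    """Percent of a group's (residue, replica) observations that stayed stable.

    100 * [1 - sum over flagged residues in the group of (replicas affected)
    / (group size after exclusions x n_replicas)].  Excluded (low-contact)
    residues do not count towards the group size.
    """
    if group not in scheme.GROUPS:
        raise ValueError(f"unknown residue group {group!r}")
    structure = contacts.structure
    excluded = set(_excluded_residues(contacts, min_contacts=min_contacts))
    group_residues = [
        r.index
        for r in structure.residues
        if r.index not in excluded and scheme.classify(r.name) == group
    ]
    if not group_residues:
        raise ValueError(f"group {group!r} is empty after exclusions")
    affected = trajectories_affected(
        [r for r in records if r.residue_index in set(group_residues)]
    )
    flagged_total = sum(affected.values())
    return 100.0 * (1.0 - flagged_total / (len(group_residues) * n_replicas))


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient.

    Requires equal lengths >= 3 and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson r needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined for zero-variance input")
    return float(_scipy_stats.pearsonr(x, y).statistic)


def correlation_table(
    per_system_q: Mapping[str, Mapping[str, float]],
    tm_records: Sequence[TmRecord],
    selections: Optional[Sequence[str]] = None,
) -> dict:
    """Pearson r of each Q selection's per-system mean against Tm.

    ``per_system_q`` maps system_id -> selection_label -> final-window mean.
    Systems missing a selection are dropped pairwise (logged).  Each entry is
    ``{"r": float or None, "n": int, "note": str}``; r is ``None`` when fewer
    than 3 systems are usable or the Q means have zero variance.
    """
    tm_by_system = {t.system_id: t.tm_celsius for t in tm_records}
    usable_systems = [s for s in per_system_q if s in tm_by_system]
    if len(usable_systems) < 3:
        raise ValueError(
            f"correlation needs >= 3 systems with both Q and Tm, got "
            f"{len(usable_systems)}"
        )
    if selections is None:
        selections = sorted({sel for s in usable_systems for sel in per_system_q[s]})

    table: dict[str, dict] = {}
    for sel in selections:
        systems = [s for s in usable_systems if sel in per_system_q[s]]
        dropped = set(usable_systems) - set(systems)
        if dropped:
            logger.warning(
                "selection %s missing for systems %s; dropped pairwise",
                sel, sorted(dropped),
            )
        note = ""
        if len(systems) < 3:
            table[sel] = {"r": None, "n": len(systems), "note": "fewer than 3 usable systems"}
            continue
        q = [per_system_q[s][sel] for s in systems]
        tm = [tm_by_system[s] for s in systems]
        try:
            r = pearson_r(q, tm)
        except ValueError:
            table[sel] = {"r": None, "n": len(systems), "note": "zero variance in Q means"}
            continue
        table[sel] = {"r": r, "n": len(systems), "note": note}
    return table


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StabilityReport:
    """Everything the protocol reports for one system.

    Every number is traceable to (system, selection, window, parameters):
    the ``provenance`` block echoes the full parameter set the report was
    computed under, and comparisons refuse reports whose provenance differs.
    """

    system_id: str
    provenance: dict
    n_replicas: int
    rmsd: WindowStats  # nm
    q: dict  # selection_label -> WindowStats
    per_residue: dict  # residue_index -> WindowStats
    unstable: list  # list of UnstableResidueRecord
    excluded_residues: list  # residue indices with < min_contacts contacts
    composition: Optional[dict]  # group -> percent, None if no flags
    residue_labels: dict  # residue_index -> author label
    tm_celsius: Optional[float] = None

    def unstable_residue_indices(self) -> list[int]:
        return sorted({r.residue_index for r in self.unstable})

    def mean_per_residue_q(self, weighted_by_contacts: bool = False,
                           contact_counts: Optional[Mapping[int, int]] = None) -> float:
        """Per-system average of the per-residue final-window Q means.

        Unweighted by default; ``weighted_by_contacts`` weights each residue
        by its native contact count (requires ``contact_counts``).
        """
        idx = sorted(self.per_residue)
        means = np.array([self.per_residue[i].mean for i in idx])
        if not weighted_by_contacts:
            return float(means.mean())
        if contact_counts is None:
            raise ValueError("contact-weighted mean needs contact_counts")
        w = np.array([contact_counts[i] for i in idx], dtype=np.float64)
        return float(np.average(means, weights=w))

    # -- serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "system_id": self.system_id,
            "provenance": self.provenance,
            "n_replicas": self.n_replicas,
            "tm_celsius": self.tm_celsius,
            "rmsd_nm": self.rmsd.as_dict(),
            "q": {sel: ws.as_dict() for sel, ws in self.q.items()},
            "per_residue": {str(i): ws.as_dict() for i, ws in self.per_residue.items()},
            "unstable": [dataclasses.asdict(r) for r in self.unstable],
            "excluded_residues": list(self.excluded_residues),
            "composition": self.composition,
            "residue_labels": {str(i): v for i, v in self.residue_labels.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "StabilityReport":
        return cls(
            system_id=d["system_id"],
            provenance=d["provenance"],
            n_replicas=d["n_replicas"],
            tm_celsius=d.get("tm_celsius"),
            rmsd=WindowStats.from_dict(d["rmsd_nm"]),
            q={sel: WindowStats.from_dict(ws) for sel, ws in d["q"].items()},
            per_residue={int(i): WindowStats.from_dict(ws) for i, ws in d["per_residue"].items()},
            unstable=[UnstableResidueRecord(**r) for r in d["unstable"]],
            excluded_residues=list(d["excluded_residues"]),
            composition=d.get("composition"),
            residue_labels={int(i): v for i, v in d["residue_labels"].items()},
        )

    @classmethod
    def from_json(cls, path) -> "StabilityReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# Table columns used for side-by-side variant comparison: RMSD plus the three
# headline Q selections.
COMPARISON_COLUMNS = ("rmsd_nm", "hydrophilic-all", "all-all", "hydrophobic-small")


def compare_variants(
    reports: Mapping[str, StabilityReport], wild_type: str
):
    """Side-by-side stability table for a wild type and its variants.

    All reports must have been computed under identical parameters
    (provenance blocks compared verbatim); otherwise the comparison is
    refused with :class:`ParameterMismatchError`.  Returns a pandas
    DataFrame with mean and SD per column and the delta of each mean vs the
    wild type.
    """
    import pandas as pd

    if wild_type not in reports:
        raise KeyError(f"wild-type report {wild_type!r} missing")
    ref_prov = reports[wild_type].provenance
    for name, rep in reports.items():
        if rep.provenance != ref_prov:
            raise ParameterMismatchError(
                f"report {name!r} was computed under different parameters than "
                f"the wild type; refusing to compare"
            )

    def _cell(rep: StabilityReport, col: str) -> WindowStats:
        return rep.rmsd if col == "rmsd_nm" else rep.q[col]

    rows = []
    order = [wild_type] + [n for n in reports if n != wild_type]
    for name in order:
        rep = reports[name]
        row: dict = {"system": name}
        for col in COMPARISON_COLUMNS:
            ws = _cell(rep, col)
            row[f"{col}_mean"] = ws.mean
            row[f"{col}_sd"] = ws.sd
            row[f"{col}_delta"] = ws.mean - _cell(reports[wild_type], col).mean
        rows.append(row)
    return pd.DataFrame(rows).set_index("system")
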