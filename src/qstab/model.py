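"""Model/Results front end tying the pipeline stages together.

:class:`StabilityModel` is constructed from a reference structure and a
trajectory ensemble (plus the analysis parameters); :meth:`StabilityModel.fit`
runs the full protocol — native contact map, backbone RMSD, Q time series
for every selection, final-window averaging, unstable-residue detection and
composition statistics — and returns a :class:`StabilityResults` carrying
the :class:`~qstab.report.StabilityReport` with a ``summary()`` table.
Cross-system statistics (Tm correlation, variant comparison) operate on
collections of results.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Optional, Sequence

import numpy as np

from .contacts import ContactParameters, NativeContactSet, build_native_contacts
from .qvalue import QParameters, contact_contributions, UndefinedQError
from .report import (
    ALL_SELECTIONS,
    StabilityReport,
    TmRecord,
    composition_stats,
    correlation_table,
    detect_unstable_residues,
)
from .series import QTimeSeries
from .structures import DEFAULT_SCHEME, ResidueGroupScheme, StructureModel
from .trajectory import (
    TrajectoryEnsemble,
    backbone_rmsd_series,
    final_window_stats,
)

__all__ = ["StabilityModel", "StabilityResults"]

logger = logging.getLogger(__name__)


class StabilityModel:
    """Thermal-stability analysis of one system.

    Parameters
    ----------
    structure : reference (native) structure; anchor of all contact
        definitions.  CDR annotation, if present, propagates into the
        unstable-residue records.
    ensemble : replica trajectories conforming to the reference atom order.
    contact_params, q_params : contact definition and Q smoothing; defaults
        are the standard soft fraction-of-native-contacts numerics
        (4.5 A, |delta res| > 3, heavy atoms; beta = 5 A^-1, lambda = 1.8).
    window_fraction : final averaging window as a fraction of each
        replica's time span (default 0.3, the final-30-of-100-ns rule).
    q_threshold : per-residue final-window mean below which a (residue,
        replica) is flagged unstable (strict; default 0.6).
    min_contacts : residues with fewer native contacts are excluded from
        flagging (default 30).
    """

    def __init__(
        self,
        structure: StructureModel,
        ensemble: TrajectoryEnsemble,
        contact_params: Optional[ContactParameters] = None,
        q_params: Optional[QParameters] = None,
        scheme: ResidueGroupScheme = DEFAULT_SCHEME,
        window_fraction: float = 0.3,
        q_threshold: float = 0.6,
        min_contacts: int = 30,
        tm_celsius: Optional[float] = None,
    ) -> None:
        self.structure = structure
        self.ensemble = ensemble
        self.contact_params = contact_params or ContactParameters()
        self.q_params = q_params or QParameters()
        self.scheme = scheme
        self.window_fraction = window_fraction
        self.q_threshold = q_threshold
        self.min_contacts = min_contacts
        self.tm_celsius = tm_celsius

    @classmethod
    def from_files(
        cls,
        structure_path,
        trajectory_paths: Sequence,
        dt_ns: Optional[float] = None,
        cdr_ranges: Optional[Sequence] = None,
        system_id: Optional[str] = None,
        **kwargs,
    ) -> "StabilityModel":
        """Build a model from a reference PDB and per-replica trajectory files."""
        from .structures import annotate_cdrs, load_structure
        from .trajectory import Replica, load_trajectory

        structure = load_structure(structure_path, source_id=system_id)
        if cdr_ranges:
            structure = annotate_cdrs(structure, cdr_ranges)
        replicas = [
            load_trajectory(p, structure, replica_id=k, dt_ns=dt_ns,
                            topology_path=structure_path)
            for k, p in enumerate(trajectory_paths)
        ]
        ensemble = TrajectoryEnsemble(
            system_id=structure.source_id, reference=structure, replicas=replicas
        )
        return cls(structure, ensemble, **kwargs)

    def provenance(self) -> dict:
        return {
            "contact_params": self.contact_params.as_dict(),
            "q_params": self.q_params.as_dict(),
            "window_fraction": self.window_fraction,
            "q_threshold": self.q_threshold,
            "min_contacts": self.min_contacts,
            "scheme": self.scheme.name,
            "backbone": ["N", "CA", "C", "O"],
        }

    def fit(self) -> "StabilityResults":
        """Run the full protocol and return the results object."""
        contacts = build_native_contacts(self.structure, self.contact_params)

        # Column index sets for every selection; the per-pair contribution
        # matrix is computed once per replica and every Q series is a column
        # mean over one of these sets.
        selection_masks: dict[str, np.ndarray] = {}
        for sel in ALL_SELECTIONS:
            ga, gb = sel.split("-")
            sub = contacts.by_groups(self.scheme, ga, gb)
            mask = _pairs_mask(contacts, sub)
            if mask.sum() == 0:
                logger.warning(
                    "selection %s has no native contacts in %s; skipped",
                    sel, self.structure.source_id,
                )
                continue
            selection_masks[sel] = mask

        residue_masks: dict[int, np.ndarray] = {}
        for res in range(self.structure.n_residues):
            sub = contacts.by_residue(res)
            mask = _pairs_mask(contacts, sub)
            if mask.sum() > 0:
                residue_masks[res] = mask

        q_series: dict[str, list[QTimeSeries]] = {s: [] for s in selection_masks}
        per_res_series: dict[int, list[QTimeSeries]] = {r: [] for r in residue_masks}
        rmsd_series = []
        for rep in self.ensemble.replicas:
            contrib = contact_contributions(rep.xyz, contacts, self.q_params)
            for sel, mask in selection_masks.items():
                q_series[sel].append(
                    QTimeSeries(
                        times=rep.times,
                        values=contrib[:, mask].mean(axis=1),
                        selection_label=sel,
                        replica_id=rep.replica_id,
                    )
                )
            for res, mask in residue_masks.items():
                per_res_series[res].append(
                    QTimeSeries(
                        times=rep.times,
                        values=contrib[:, mask].mean(axis=1),
                        selection_label=f"residue:{self.structure.residue_label(res)}",
                        replica_id=rep.replica_id,
                    )
                )
            rmsd_series.append(backbone_rmsd_series(rep, self.structure))

        wf = self.window_fraction
        rmsd_stats = final_window_stats(rmsd_series, wf)
        q_stats = {sel: final_window_stats(sl, wf) for sel, sl in q_series.items()}
        per_res_stats = {
            res: final_window_stats(sl, wf) for res, sl in per_res_series.items()
        }

        records, excluded = detect_unstable_residues(
            per_res_stats, contacts,
            q_threshold=self.q_threshold, min_contacts=self.min_contacts,
        )
        composition = composition_stats(records, self.scheme)

        report = StabilityReport(
            system_id=self.ensemble.system_id,
            provenance=self.provenance(),
            n_replicas=self.ensemble.n_replicas,
            rmsd=rmsd_stats,
            q=q_stats,
            per_residue=per_res_stats,
            unstable=records,
            excluded_residues=excluded,
            composition=composition,
            residue_labels={
                r.index: r.label for r in self.structure.residues
            },
            tm_celsius=self.tm_celsius,
        )
        return StabilityResults(
            model=self,
            report=report,
            contacts=contacts,
            q_series=q_series,
            per_residue_series=per_res_series,
            rmsd_series=rmsd_series,
        )


def _pairs_mask(full: NativeContactSet, subset: NativeContactSet) -> np.ndarray:
    """Boolean column mask of ``subset``'s pairs within ``full``'s pair list."""
    # subsets produced by masking preserve pair order, so match on the
    # (atom_i, atom_j) key arrays
    full_keys = full.atom_i * full.structure.n_atoms + full.atom_j
    sub_keys = subset.atom_i * full.structure.n_atoms + subset.atom_j
    return np.isin(full_keys, sub_keys)


class StabilityResults:
    """Fitted stability analysis of one system.

    Carries the :class:`StabilityReport` (estimates, spreads, flags), the
    native contact set, and every intermediate time series; ``summary()``
    renders the headline table.
    """

    def __init__(self, model, report, contacts, q_series, per_residue_series,
                 rmsd_series) -> None:
        self.model = model
        self.report = report
        self.contacts = contacts
        self.q_series = q_series
        self.per_residue_series = per_residue_series
        self.rmsd_series = rmsd_series

    # convenience accessors -------------------------------------------------
    @property
    def q_mean(self) -> dict:
        return {sel: ws.mean for sel, ws in self.report.q.items()}

    @property
    def unstable(self):
        return self.report.unstable

    def native_q(self, selection: str = "all-all") -> float:
        """Q of the reference structure itself under the fitted parameters."""
        from .qvalue import soft_q

        sub = self.contacts if selection == "all-all" else self.contacts.by_groups(
            self.model.scheme, *selection.split("-")
        )
        return soft_q(self.model.structure.coords, sub, self.model.q_params)

    def summary(self) -> str:
        rep = self.report
        lines = []
        lines.append(f"Stability analysis: {rep.system_id}")
        lines.append("=" * 58)
        lines.append(
            f"replicas: {rep.n_replicas}   window fraction: "
            f"{rep.provenance['window_fraction']}   "
            f"cutoff: {rep.provenance['contact_params']['cutoff']} A   "
            f"beta: {rep.provenance['q_params']['beta']}   "
            f"lambda: {rep.provenance['q_params']['lam']}"
        )
        lines.append(f"native contacts: {len(self.contacts)}")
        lines.append("-" * 58)
        lines.append(f"{'selection':<28s}{'mean Q':>10s}{'SD':>10s}{'frames':>8s}")
        for sel in rep.q:
            ws = rep.q[sel]
            lines.append(f"{sel:<28s}{ws.mean:>10.4f}{ws.sd:>10.4f}{ws.n_frames:>8d}")
        lines.append(
            f"{'backbone RMSD (nm)':<28s}{rep.rmsd.mean:>10.4f}{rep.rmsd.sd:>10.4f}"
            f"{rep.rmsd.n_frames:>8d}"
        )
        lines.append("-" * 58)
        flagged = rep.unstable_residue_indices()
        lines.append(
            f"unstable residues (< {rep.provenance['q_threshold']}): "
            f"{len(flagged)}"
        )
        for idx in flagged:
            recs = [r for r in rep.unstable if r.residue_index == idx]
            star = "*" if recs[0].in_cdr else " "
            mean_q = np.mean([r.mean_q_final_window for r in recs])
            lines.append(
                f"  {recs[0].residue_label:<10s}{star} replicas affected: "
                f"{len(recs):>2d}   mean Q: {mean_q:.3f}"
            )
        lines.append(
            f"excluded residues (< {rep.provenance['min_contacts']} contacts): "
            + (", ".join(rep.residue_labels[i] for i in rep.excluded_residues) or "none")
        )
        if rep.composition is not None:
            comp = "  ".join(f"{g}: {p:.1f}%" for g, p in rep.composition.items())
            lines.append(f"unstable composition (trajectory-weighted): {comp}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<StabilityResults {self.report.system_id}: "
            f"Q(all-all)={self.report.q['all-all'].mean:.3f}>"
        )

    # cross-system helpers ---------------------------------------------------
    @staticmethod
    def correlate(results: Sequence["StabilityResults"],
                  tm_records: Sequence[TmRecord],
                  selections: Optional[Sequence[str]] = None) -> dict:
        """Pearson r of each selection's per-system mean Q against Tm."""
        per_system = {
            res.report.system_id: res.q_mean for res in results
        }
        return correlation_table(per_system, tm_records, selections)
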