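"""Decision rules: unstable-residue flags, compositions, correlations, comparisons."""

import numpy as np
import pytest

from qstab.contacts import build_native_contacts
from qstab.report import (
    ParameterMismatchError,
    StabilityReport,
    TmRecord,
    UnstableResidueRecord,
    compare_variants,
    composition_stats,
    correlation_table,
    detect_unstable_residues,
    group_stability_fraction,
    pearson_r,
    trajectories_affected,
)
from qstab.structures import DEFAULT_SCHEME
from qstab.trajectory import WindowStats

from conftest import random_structure

# Tm values of seven single-domain antibodies spanning ~47-85 degC, the kind
# of spread the correlation stage is designed for.
TM_TABLE = [
    TmRecord("4idl", 46.75), TmRecord("1fvc", 58.00), TmRecord("4w70", 60.00),
    TmRecord("1mel", 69.00), TmRecord("5sv4", 70.70), TmRecord("3b9v", 79.00),
    TmRecord("4tyu", 85.00),
]


def make_window_stats(per_replica_means, t_end=100.0):
    means = list(per_replica_means)
    return WindowStats(
        mean=float(np.mean(means)), sd=float(np.std(means)),
        n_frames=10 * len(means), window=(70.0, t_end),
        per_replica_means=means, replica_ids=list(range(len(means))),
    )


@pytest.fixture
def contacts():
    return build_native_contacts(random_structure(200, seed=17))


class TestDetectUnstableResidues:
    def test_strict_threshold_boundary(self, contacts):
        counts = contacts.per_residue_counts
        rich = [int(r) for r in np.argsort(counts)[::-1][:2]]
        stats = {
            rich[0]: make_window_stats([0.59, 0.95, 0.95]),
            rich[1]: make_window_stats([0.60, 0.95, 0.95]),
        }
        records, _ = detect_unstable_residues(
            stats, contacts, q_threshold=0.6, min_contacts=0
        )
        flagged = {(r.residue_index, r.replica_id) for r in records}
        assert flagged == {(rich[0], 0)}  # 0.59 flags, 0.60 does not
        assert records[0].mean_q_final_window == pytest.approx(0.59)

    def test_low_contact_residue_excluded_not_flagged(self, contacts):
        counts = contacts.per_residue_counts
        poor = int(np.argmin(counts))  # certainly < 30 in a random scatter
        stats = {poor: make_window_stats([0.1, 0.1])}
        records, excluded = detect_unstable_residues(
            stats, contacts, min_contacts=counts[poor] + 1
        )
        assert poor in excluded
        assert all(r.residue_index != poor for r in records)

    def test_exclusion_boundary_29_vs_30(self, contacts):
        counts = contacts.per_residue_counts
        res = int(np.argmax(counts))
        stats = {res: make_window_stats([0.1])}
        # min_contacts above the residue's count -> excluded (strict <)
        _, excl = detect_unstable_residues(stats, contacts,
                                           min_contacts=counts[res] + 1)
        assert res in excl
        # equal to the count -> included and flagged
        recs, excl = detect_unstable_residues(stats, contacts,
                                              min_contacts=counts[res])
        assert res not in excl
        assert recs and recs[0].residue_index == res

    def test_flag_monotonicity_in_threshold(self, contacts):
        rng = np.random.default_rng(5)
        stats = {
            r: make_window_stats(rng.uniform(0.3, 1.0, size=4))
            for r in range(contacts.structure.n_residues)
        }
        low, _ = detect_unstable_residues(stats, contacts, q_threshold=0.5,
                                          min_contacts=0)
        high, _ = detect_unstable_residues(stats, contacts, q_threshold=0.7,
                                           min_contacts=0)
        low_keys = {(r.residue_index, r.replica_id) for r in low}
        high_keys = {(r.residue_index, r.replica_id) for r in high}
        assert low_keys <= high_keys

    def test_flag_monotonicity_in_min_contacts(self, contacts):
        stats = {
            r: make_window_stats([0.2, 0.2])
            for r in range(contacts.structure.n_residues)
        }
        few, _ = detect_unstable_residues(stats, contacts, min_contacts=40)
        many, _ = detect_unstable_residues(stats, contacts, min_contacts=10)
        few_keys = {(r.residue_index, r.replica_id) for r in few}
        many_keys = {(r.residue_index, r.replica_id) for r in many}
        assert few_keys <= many_keys


def record(res, name, rep, q=0.5, in_cdr=False):
    return UnstableResidueRecord(res, f"{name.capitalize()}{res+1}", name,
                                 rep, q, in_cdr)


class TestCompositionStats:
    def test_two_residue_arithmetic(self):
        # one hydrophilic residue (2 replicas) + one small residue (2
        # replicas) -> 50 / 0 / 50
        recs = [record(0, "ASP", 0), record(0, "ASP", 1),
                record(1, "GLY", 0), record(1, "GLY", 1)]
        comp = composition_stats(recs, DEFAULT_SCHEME)
        assert comp == {"hydrophilic": 50.0, "hydrophobic": 0.0, "small": 50.0}

    def test_all_hydrophobic(self):
        recs = [record(0, "PHE", 0), record(1, "TRP", 0), record(1, "TRP", 1)]
        comp = composition_stats(recs, DEFAULT_SCHEME)
        assert comp == {"hydrophilic": 0.0, "hydrophobic": 100.0, "small": 0.0}

    def test_trajectory_weighting(self):
        # hydrophilic flagged in 3 replicas, small in 1 -> 75 / 25
        recs = [record(0, "LYS", r) for r in range(3)] + [record(1, "SER", 0)]
        comp = composition_stats(recs, DEFAULT_SCHEME)
        assert comp["hydrophilic"] == pytest.approx(75.0)
        assert comp["small"] == pytest.approx(25.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(9)
        names = ["ASP", "PHE", "GLY", "LYS", "TRP", "SER", "ALA", "GLU"]
        recs = [
            record(i, names[i % len(names)], rep)
            for i in range(8) for rep in range(int(rng.integers(1, 5)))
        ]
        comp = composition_stats(recs, DEFAULT_SCHEME)
        assert sum(comp.values()) == pytest.approx(100.0, abs=1e-9)

    def test_no_flags_undefined(self):
        assert composition_stats([], DEFAULT_SCHEME) is None


class TestGroupStabilityFraction:
    def test_no_flags_means_100(self, contacts):
        pct = group_stability_fraction([], contacts, DEFAULT_SCHEME,
                                       "hydrophilic", n_replicas=10,
                                       min_contacts=0)
        assert pct == 100.0

    def test_designed_arithmetic(self, contacts):
        # flag one hydrophilic residue in all 10 replicas; with n group
        # residues the stable fraction is 100 * (1 - 10 / (n * 10))
        structure = contacts.structure
        group_res = [
            r.index for r in structure.residues
            if DEFAULT_SCHEME.classify(r.name) == "hydrophilic"
        ]
        target = group_res[0]
        recs = [record(target, structure.residues[target].name, rep)
                for rep in range(10)]
        pct = group_stability_fraction(recs, contacts, DEFAULT_SCHEME,
                                       "hydrophilic", n_replicas=10,
                                       min_contacts=0)
        assert pct == pytest.approx(100.0 * (1 - 1 / len(group_res)))

    def test_unknown_group(self, contacts):
        with pytest.raises(ValueError):
            group_stability_fraction([], contacts, DEFAULT_SCHEME, "polar", 10)


class TestPearson:
    def test_identity(self):
        tm = [t.tm_celsius for t in TM_TABLE]
        assert pearson_r(tm, tm) == pytest.approx(1.0)

    def test_antisymmetry(self):
        tm = np.array([t.tm_celsius for t in TM_TABLE])
        assert pearson_r(tm, -tm) == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        assert pearson_r(x, 3.5 * x + 2.0) == pytest.approx(1.0, abs=1e-12)

    def test_guards(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [1, 2])
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1, 2, 3])


class TestCorrelationTable:
    def per_system(self, qs):
        return {t.system_id: {"all-all": q} for t, q in zip(TM_TABLE, qs)}

    def test_reproduces_pearson_exactly(self):
        rng = np.random.default_rng(7)
        qs = rng.uniform(0.6, 1.0, size=7)
        table = correlation_table(self.per_system(qs), TM_TABLE)
        expected = pearson_r(qs, [t.tm_celsius for t in TM_TABLE])
        assert table["all-all"]["r"] == pytest.approx(expected, abs=0)
        assert table["all-all"]["n"] == 7

    def test_system_order_invariance(self):
        rng = np.random.default_rng(8)
        qs = rng.uniform(0.6, 1.0, size=7)
        t1 = correlation_table(self.per_system(qs), TM_TABLE)
        shuffled = dict(reversed(list(self.per_system(qs).items())))
        t2 = correlation_table(shuffled, list(reversed(TM_TABLE)))
        assert t1["all-all"]["r"] == pytest.approx(t2["all-all"]["r"], abs=1e-15)

    def test_zero_variance_reported_undefined(self):
        table = correlation_table(self.per_system([0.9] * 7), TM_TABLE)
        assert table["all-all"]["r"] is None
        assert "variance" in table["all-all"]["note"]

    def test_fewer_than_three_systems_rejected(self):
        two = {"4idl": {"all-all": 0.9}, "1fvc": {"all-all": 0.8}}
        with pytest.raises(ValueError):
            correlation_table(two, TM_TABLE[:2])

    def test_missing_selection_dropped_pairwise(self):
        per_system = self.per_system(np.linspace(0.7, 0.95, 7))
        del per_system["1mel"]["all-all"]
        per_system["1mel"]["other"] = 0.5
        table = correlation_table(per_system, TM_TABLE, selections=["all-all"])
        assert table["all-all"]["n"] == 6


def minimal_report(system_id, q_all, q_phil, q_phob_small, rmsd=0.2,
                   provenance=None):
    prov = provenance if provenance is not None else {"beta": 5.0}
    ws = lambda m: WindowStats(m, 0.01, 100, (70.0, 100.0), [m], [0])
    return StabilityReport(
        system_id=system_id, provenance=prov, n_replicas=1,
        rmsd=ws(rmsd),
        q={"all-all": ws(q_all), "hydrophilic-all": ws(q_phil),
           "hydrophobic-small": ws(q_phob_small)},
        per_residue={}, unstable=[], excluded_residues=[],
        composition=None, residue_labels={},
    )


class TestCompareVariants:
    def test_self_comparison_zero_deltas(self):
        wt = minimal_report("wt", 0.91, 0.87, 0.94)
        table = compare_variants({"wt": wt}, "wt")
        for col in ("rmsd_nm", "all-all", "hydrophilic-all", "hydrophobic-small"):
            assert table.loc["wt", f"{col}_delta"] == 0.0

    def test_stabilized_mutant_positive_deltas(self):
        wt = minimal_report("wt", 0.91, 0.87, 0.94)
        mut = minimal_report("mut", 0.95, 0.92, 0.97)
        table = compare_variants({"wt": wt, "mut": mut}, "wt")
        for col in ("all-all", "hydrophilic-all", "hydrophobic-small"):
            assert table.loc["mut", f"{col}_delta"] > 0

    def test_parameter_mismatch_refused(self):
        wt = minimal_report("wt", 0.91, 0.87, 0.94, provenance={"lam": 1.8})
        mut = minimal_report("mut", 0.95, 0.92, 0.97, provenance={"lam": 2.0})
        with pytest.raises(ParameterMismatchError):
            compare_variants({"wt": wt, "mut": mut}, "wt")

    def test_missing_wild_type(self):
        with pytest.raises(KeyError):
            compare_variants({}, "wt")


class TestReportSerialization:
    def test_json_roundtrip(self, tmp_path):
        rep = minimal_report("sys1", 0.91, 0.87, 0.94)
        rep.unstable = [record(3, "ASP", 1, q=0.4, in_cdr=True)]
        rep.excluded_residues = [0, 9]
        rep.residue_labels = {0: "Lys1", 3: "Asp4", 9: "Gly10"}
        path = tmp_path / "rep.json"
        rep.to_json(path)
        back = StabilityReport.from_json(path)
        assert back.system_id == rep.system_id
        assert back.q["all-all"].mean == rep.q["all-all"].mean
        assert back.unstable == rep.unstable
        assert back.excluded_residues == [0, 9]

    def test_trajectories_affected(self):
        recs = [record(0, "ASP", 0), record(0, "ASP", 2), record(5, "GLY", 1)]
        assert trajectories_affected(recs) == {0: 2, 5: 1}
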