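"""Soft Q kernel: closed-form values, naive-loop oracle, decomposition identities."""

import math

import numpy as np
import pytest

from qstab.contacts import build_native_contacts, mask_by_groups, mask_by_residue
from qstab.qvalue import (
    Frame,
    QParameters,
    UndefinedQError,
    contact_contributions,
    group_pair_q_series,
    per_residue_q_series,
    q_timeseries,
    soft_q,
)
from qstab.structures import DEFAULT_SCHEME, Atom, Residue, StructureModel
from qstab.trajectory import Replica

from conftest import random_structure


def naive_q(xyz, contacts, params):
    """Per-pair python loop; the independent oracle for the vectorized kernel."""
    total = 0.0
    for ai, aj, r0 in zip(contacts.atom_i, contacts.atom_j, contacts.r0):
        r = math.dist(xyz[ai], xyz[aj])
        total += 1.0 / (1.0 + math.exp(min(params.beta * (r - params.lam * r0), 700.0)))
    return total / len(contacts)


def single_contact_structure(r0=4.0):
    residues = [Residue(i, "ALA", i + 1, " ", "A") for i in range(10)]
    atoms = [
        Atom(1, "CA", "C", 0, "ALA", "A", np.zeros(3)),
        Atom(2, "CA", "C", 9, "ALA", "A", np.array([r0, 0.0, 0.0])),
    ]
    s = StructureModel(atoms, residues)
    return s, build_native_contacts(s)


class TestSoftQ:
    def test_logistic_midpoint_is_half(self):
        s, c = single_contact_structure(r0=4.0)
        params = QParameters()
        xyz = s.coords.copy()
        xyz[1, 0] = params.lam * 4.0  # r = lambda * r0
        assert soft_q(xyz, c, params) == pytest.approx(0.5, abs=1e-15)

    def test_far_limit_goes_to_zero(self):
        s, c = single_contact_structure()
        xyz = s.coords.copy()
        xyz[1, 0] = 1e3
        q = soft_q(xyz, c)
        assert 0.0 <= q <= 1e-12

    def test_native_single_contact_value(self):
        # r = r0 = 4.4, beta = 5, lam = 1.8: Q = 1/(1+exp(5*(4.4-1.8*4.4)))
        #                                      = 1/(1+e^-17.6)
        s, c = single_contact_structure(r0=4.4)
        expected = 1.0 / (1.0 + math.exp(5.0 * 4.4 * (1.0 - 1.8)))
        assert soft_q(s.coords, c) == pytest.approx(expected, abs=1e-15)
        assert expected > 0.99999997

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_loop(self, seed):
        s = random_structure(60, seed=seed)
        c = build_native_contacts(s)
        rng = np.random.default_rng(seed + 100)
        xyz = s.coords + rng.normal(0, 2.0, size=s.coords.shape)
        params = QParameters()
        assert soft_q(xyz, c, params) == pytest.approx(
            naive_q(xyz, c, params), abs=1e-12
        )

    def test_empty_selection_rejected(self):
        s = random_structure(60, seed=1)
        c = build_native_contacts(s)
        empty = c.subset(np.zeros(len(c), dtype=bool), "empty")
        with pytest.raises(UndefinedQError):
            soft_q(s.coords, empty)

    def test_atom_count_mismatch(self):
        s, c = single_contact_structure()
        with pytest.raises(ValueError):
            soft_q(np.zeros((5, 3)), c)

    def test_bounds_and_frame_object(self):
        s = random_structure(80, seed=7)
        c = build_native_contacts(s)
        q = soft_q(Frame(xyz=s.coords), c)
        assert 0.0 < q < 1.0

    def test_uniform_expansion_decreases_q(self):
        # all pair distances grow under uniform scaling about the centroid,
        # so every logistic term and hence Q strictly decreases
        s = random_structure(80, seed=12)
        c = build_native_contacts(s)
        centroid = s.coords.mean(axis=0)
        q_native = soft_q(s.coords, c)
        prev = q_native
        for scale in (1.5, 2.0, 3.0):
            q = soft_q(centroid + scale * (s.coords - centroid), c)
            assert q < prev
            prev = q


def _native_replica(structure, n_frames=5):
    xyz = np.repeat(structure.coords[None], n_frames, axis=0)
    return Replica(replica_id=0, times=np.arange(1.0, n_frames + 1), xyz=xyz)


class TestQTimeSeries:
    def test_native_trajectory_constant_high(self):
        s = random_structure(90, seed=3)
        c = build_native_contacts(s)
        ts = q_timeseries(_native_replica(s), c)
        assert np.all(ts.values > 0.99)
        assert np.ptp(ts.values) == 0.0

    def test_deterministic(self):
        s = random_structure(90, seed=3)
        c = build_native_contacts(s)
        rng = np.random.default_rng(0)
        rep = Replica(0, np.arange(1.0, 6.0),
                      s.coords[None] + rng.normal(0, 1, (5, s.n_atoms, 3)))
        np.testing.assert_array_equal(
            q_timeseries(rep, c).values, q_timeseries(rep, c).values
        )

    def test_chunking_matches_unchunked(self):
        s = random_structure(90, seed=3)
        c = build_native_contacts(s)
        rng = np.random.default_rng(5)
        rep = Replica(0, np.arange(1.0, 21.0),
                      s.coords[None] + rng.normal(0, 1, (20, s.n_atoms, 3)))
        np.testing.assert_allclose(
            q_timeseries(rep, c, chunk_frames=3).values,
            q_timeseries(rep, c, chunk_frames=1000).values,
            atol=1e-15,
        )

    def test_scaled_frames_lower_than_native(self):
        s = random_structure(90, seed=3)
        c = build_native_contacts(s)
        centroid = s.coords.mean(axis=0)
        scaled = centroid + 2.0 * (s.coords - centroid)
        rep = Replica(0, np.array([1.0, 2.0]), np.stack([s.coords, scaled]))
        ts = q_timeseries(rep, c)
        assert ts.values[1] < ts.values[0]


class TestDecompositionIdentities:
    @pytest.fixture
    def system(self):
        s = random_structure(150, seed=21)
        c = build_native_contacts(s)
        rng = np.random.default_rng(42)
        xyz = s.coords[None] + rng.normal(0, 1.5, (6, s.n_atoms, 3))
        rep = Replica(0, np.arange(1.0, 7.0), xyz)
        return s, c, rep

    def test_group_pair_weighted_identity(self, system):
        # N_all * Q_all(t) = sum over the six disjoint group pairs of N * Q(t)
        s, c, rep = system
        q_all = q_timeseries(rep, c).values * len(c)
        groups = DEFAULT_SCHEME.GROUPS
        acc = np.zeros_like(q_all)
        for k, ga in enumerate(groups):
            for gb in groups[k:]:
                sub = mask_by_groups(c, DEFAULT_SCHEME, ga, gb)
                if len(sub) == 0:
                    continue
                acc += q_timeseries(rep, sub).values * len(sub)
        np.testing.assert_allclose(acc, q_all, atol=1e-10)

    def test_per_residue_weighted_identity(self, system):
        # contact-count-weighted mean of per-residue Q (each pair counted
        # twice) equals the all-all Q at every frame
        s, c, rep = system
        q_all = q_timeseries(rep, c).values
        num = np.zeros_like(q_all)
        denom = 0.0
        for res in range(s.n_residues):
            sub = mask_by_residue(c, res)
            if len(sub) == 0:
                continue
            num += q_timeseries(rep, sub).values * len(sub)
            denom += len(sub)
        np.testing.assert_allclose(num / denom, q_all, atol=1e-10)

    def test_group_series_label_and_identity(self, system):
        s, c, rep = system
        ts = group_pair_q_series(rep, c, DEFAULT_SCHEME, "all", "all")
        np.testing.assert_array_equal(ts.values, q_timeseries(rep, c).values)
        assert ts.selection_label == "all-all"


class TestPerResidueSeries:
    def test_displaced_residue_detected(self):
        # displace only residue k's atoms far away: its Q collapses while
        # residues sharing no contacts with k stay native
        s = random_structure(150, seed=33)
        c = build_native_contacts(s)
        k = int(np.argmax(c.per_residue_counts))
        atom_mask = np.array([a.residue_index == k for a in s.atoms])
        moved = s.coords.copy()
        moved[atom_mask] += 20.0
        rep = Replica(0, np.array([1.0]), moved[None])

        q_k = per_residue_q_series(rep, c, k).values[0]
        assert q_k < 0.05
        partners = set(c.res_i[c.res_j == k]) | set(c.res_j[c.res_i == k])
        for res in range(s.n_residues):
            if res == k or res in partners:
                continue
            sub = mask_by_residue(c, res)
            if len(sub) == 0:
                continue
            assert per_residue_q_series(rep, c, res).values[0] > 0.99

    def test_contact_free_residue_undefined(self):
        # residue 2 sits 100 A away from everything: no native contacts
        residues = [Residue(i, "ALA", i + 1, " ", "A") for i in range(12)]
        atoms = []
        rng = np.random.default_rng(8)
        serial = 0
        for i in range(12):
            base = (np.array([100.0, 100.0, 100.0]) if i == 2
                    else rng.uniform(0, 10, 3))
            serial += 1
            atoms.append(Atom(serial, "CA", "C", i, "ALA", "A", base))
        s = StructureModel(atoms, residues)
        c = build_native_contacts(s)
        assert c.per_residue_counts[2] == 0
        rep = _native_replica(s, 2)
        with pytest.raises(UndefinedQError):
            per_residue_q_series(rep, c, 2)


class TestQParameters:
    def test_validation(self):
        with pytest.raises(ValueError):
            QParameters(beta=0.0)
        with pytest.raises(ValueError):
            QParameters(lam=0.5)

    def test_contributions_shape(self):
        s = random_structure(60, seed=2)
        c = build_native_contacts(s)
        xyz = np.repeat(s.coords[None], 4, axis=0)
        contrib = contact_contributions(xyz, c)
        assert contrib.shape == (4, len(c))
        assert np.all((contrib > 0) & (contrib < 1))
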