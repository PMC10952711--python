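"""Pairwise similarity metrics: hand cases, oracles and invariances."""

import numpy as np
import pytest

from assemblyqa.decoys import DecoyEnsembleSpec, NoiseTier, make_decoys, _helix_atoms
from assemblyqa.metrics import (
    ContactMap,
    DegenerateSuperpositionError,
    MetricParams,
    compute_contact_map,
    compute_dockq,
    compute_ics_ips,
    compute_oligo_lddt,
    compute_pairwise_scores,
    compute_qs,
    compute_tm,
    dockq_from_terms,
    kabsch_superpose,
)
from conftest import toy_model

RNG = np.random.default_rng(2024)


def small_dimer(n_res: int = 12, model_id: str = "small") -> "StructureModel":
    """Two short helices, well under the oracle size limit."""
    chains = {}
    for cid, off in (("A", (0.0, 0.0, 0.0)), ("B", (9.5, 0.0, 0.0))):
        atoms = _helix_atoms(n_res)
        chains[cid] = [
            (i + 1, "ALA", {k: tuple(np.asarray(v) + off) for k, v in a.items()})
            for i, a in enumerate(atoms)
        ]
    m = toy_model(chains, model_id=model_id)
    return m


def rigid_transform(model, rot, trans, model_id="moved"):
    chains = {
        c.chain_id: [(r.number, r.name,
                      {k: tuple(rot @ v + trans) for k, v in r.atoms.items()})
                     for r in c.residues]
        for c in model.chains
    }
    return toy_model(chains, model_id=model_id)


def rotation_z(angle_deg):
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestKabsch:
    def test_identity(self):
        pts = RNG.normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_pure_translation_removed(self):
        pts = RNG.normal(size=(8, 3))
        _, _, rmsd = kabsch_superpose(pts, pts + np.array([5.0, 0, 0]))
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_known_rotation_recovered(self):
        pts = RNG.normal(size=(20, 3))
        rot_true = rotation_z(30.0)
        moved = pts @ rot_true.T
        rot, _, rmsd = kabsch_superpose(pts, moved)
        assert rmsd <= 1e-6
        assert np.allclose(rot @ rot_true, np.eye(3), atol=1e-6)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_shape_and_degeneracy_errors(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(DegenerateSuperpositionError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestContactMap:
    def test_separated_chains_empty(self):
        m = toy_model({"A": [(1, "GLY", {"CA": (0, 0, 0)})],
                       "B": [(1, "GLY", {"CA": (100, 0, 0)})]})
        assert len(compute_contact_map(m, 5.0)) == 0

    def test_hand_geometry_single_contact(self):
        m = toy_model({"A": [(1, "GLY", {"CA": (0, 0, 0)})],
                       "B": [(1, "GLY", {"CA": (4.0, 0, 0)})]})
        cmap = compute_contact_map(m, 5.0)
        assert len(cmap) == 1
        ((pair, dist),) = cmap.contacts.items()
        assert pair == (("A", 1), ("B", 1))
        assert dist == pytest.approx(4.0)
        assert cmap.interface_residues == {("A", 1), ("B", 1)}

    def test_zero_cutoff_empty(self, homo_native):
        assert len(compute_contact_map(homo_native, 0.0)) == 0

    def test_matches_brute_force(self):
        model = small_dimer()
        cmap = compute_contact_map(model, 5.0)
        # all-pairs brute force over heavy atoms
        expected = {}
        for c1 in model.chains:
            for c2 in model.chains:
                if c1.chain_id >= c2.chain_id:
                    continue
                for r1 in c1.residues:
                    for r2 in c2.residues:
                        d = min(np.linalg.norm(a - b)
                                for a in r1.atoms.values() for b in r2.atoms.values())
                        if d <= 5.0:
                            expected[((c1.chain_id, r1.number), (c2.chain_id, r2.number))] = d
        assert set(cmap.contacts) == set(expected)
        for k in expected:
            assert cmap.contacts[k] == pytest.approx(expected[k], abs=1e-9)


class TestOligoLddt:
    def test_identity_is_one(self, homo_native):
        assert compute_oligo_lddt(homo_native, homo_native) == 1.0

    def test_single_pair_hand_case(self):
        ref = toy_model({"A": [(1, "ALA", {"CA": (0, 0, 0)}),
                               (2, "ALA", {"CA": (4.0, 0, 0)})]}, model_id="ref")
        mod = toy_model({"A": [(1, "ALA", {"CA": (0, 0, 0)}),
                               (2, "ALA", {"CA": (4.9, 0, 0)})]}, model_id="mod")
        # |4.9 - 4.0| = 0.9: fails 0.5, passes 1/2/4 -> 3/4
        assert compute_oligo_lddt(mod, ref) == pytest.approx(0.75)

    def test_missing_atoms_fail_all_thresholds(self):
        ref = toy_model({"A": [(1, "ALA", {"CA": (0, 0, 0)}),
                               (2, "ALA", {"CA": (4.0, 0, 0)})]}, model_id="ref")
        # model chain misses residue 2 entirely -> the only assessed pair fails
        mod = toy_model({"A": [(1, "ALA", {"CA": (0, 0, 0)}),
                               (3, "GLY", {"CA": (50.0, 0, 0)})]}, model_id="mod")
        assert compute_oligo_lddt(mod, ref) <= 0.25


class TestDockq:
    def test_identity(self, hetero_native):
        dockq, fnat, irms, lrms = compute_dockq(hetero_native, hetero_native)
        assert fnat == 1.0
        assert irms == pytest.approx(0.0, abs=1e-9)
        assert lrms == pytest.approx(0.0, abs=1e-9)
        assert dockq == pytest.approx(1.0, abs=1e-12)

    def test_formula_half_points(self):
        assert dockq_from_terms(0.5, 1.5, 8.5) == pytest.approx(0.5, abs=1e-15)
        assert dockq_from_terms(1.0, 0.0, 0.0) == 1.0

    def test_dissociated_interface_small_positive(self, hetero_native):
        far = rigid_transform(hetero_native, np.eye(3), np.zeros(3))
        for res in far.chains[1].residues:
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + np.array([500.0, 0, 0])
        dockq, fnat, _, _ = compute_dockq(far, hetero_native)
        assert fnat == 0.0
        assert 0.0 < dockq < 0.05

    def test_fnat_matches_brute_force(self, mild_tier):
        ref = small_dimer(model_id="ref")
        spec = DecoyEnsembleSpec(n_chains=2, chain_lengths=(24, 24), seed=5, n_decoys=1,
                                 noise_ladder=(mild_tier,))
        model = small_dimer(model_id="mod")
        rng = np.random.default_rng(7)
        for c in model.chains:
            for r in c.residues:
                for k in r.atoms:
                    r.atoms[k] = r.atoms[k] + rng.normal(0, 1.0, 3)
        _, fnat, _, _ = compute_dockq(model, ref)

        def contacts(m):
            out = set()
            for c1 in m.chains:
                for c2 in m.chains:
                    if c1.chain_id >= c2.chain_id:
                        continue
                    for r1 in c1.residues:
                        for r2 in c2.residues:
                            d = min(np.linalg.norm(a - b)
                                    for a in r1.atoms.values() for b in r2.atoms.values())
                            if d <= 5.0:
                                out.add(((c1.chain_id, r1.number), (c2.chain_id, r2.number)))
            return out

        ref_c, mod_c = contacts(ref), contacts(model)
        assert fnat == pytest.approx(len(ref_c & mod_c) / len(ref_c), abs=1e-9)


class TestQs:
    def test_identity(self, homo_native):
        assert compute_qs(homo_native, homo_native) == 1.0
        assert compute_qs(homo_native, homo_native, dialect="official") == 1.0

    def test_weight_ramp_hand_case(self):
        ref = toy_model({"A": [(1, "ALA", {"CA": (0, 0, 0), "CB": (0, 0, 0)})],
                         "B": [(1, "ALA", {"CA": (8.5, 0, 0), "CB": (8.5, 0, 0)})]},
                        model_id="ref")
        mod = toy_model({"A": [(1, "ALA", {"CA": (0, 0, 0), "CB": (0, 0, 0)})],
                         "B": [(1, "ALA", {"CA": (5.0, 0, 0), "CB": (5.0, 0, 0)})]},
                        model_id="mod")
        # model weight 1.0, reference weight (12-8.5)/7 = 0.5
        assert compute_qs(mod, ref) == pytest.approx(0.5)
        assert compute_qs(mod, ref, dialect="official") == 1.0

    def test_disjoint_contacts_zero(self):
        # distinct chain sequences pin the mapping to identity; the single
        # model contact and single reference contact involve different pairs
        def dimer(b1_y, b2_y, mid):
            return toy_model({
                "A": [(1, "ALA", {"CB": (0, 0, 0)}), (2, "TRP", {"CB": (0, 0, 30)})],
                "B": [(1, "PHE", {"CB": (0, b1_y, 0)}), (2, "LYS", {"CB": (0, b2_y, 30)})],
            }, model_id=mid)

        ref = dimer(5.0, 50.0, "ref")     # only A1-B1 in contact
        mod = dimer(50.0, 5.0, "mod")     # only A2-B2 in contact
        assert compute_qs(mod, ref) == 0.0

    def test_symmetric(self, homo_native, homo_decoys):
        d = homo_decoys[3]
        for dialect in ("weighted", "official"):
            ab = compute_qs(d, homo_native, dialect=dialect)
            ba = compute_qs(homo_native, d, dialect=dialect)
            assert ab == pytest.approx(ba, abs=1e-12)


class TestIcsIps:
    def test_set_arithmetic_example(self):
        def cmap(pairs):
            return ContactMap({tuple(sorted(p)): 1.0 for p in pairs}, 5.0)

        model = cmap([(("A", 1), ("B", 1)), (("A", 2), ("B", 2))])
        ref = cmap([(("A", 2), ("B", 2)), (("A", 3), ("B", 3))])
        ics, ips = compute_ics_ips(model, ref)
        assert ics == pytest.approx(0.5)
        assert ips == pytest.approx(1.0 / 3.0)

    def test_identity(self):
        m = ContactMap({(("A", 1), ("B", 1)): 2.0}, 5.0)
        assert compute_ics_ips(m, m) == (1.0, 1.0)


class TestTm:
    def test_identity(self, hetero_native):
        assert compute_tm(hetero_native, hetero_native) == pytest.approx(1.0, abs=1e-12)

    def test_d0_formula(self):
        # L=40: d0 = 1.24 * 25^(1/3) - 1.8
        assert 1.24 * 25 ** (1 / 3) - 1.8 == pytest.approx(1.826, abs=5e-4)

    def test_matches_randomized_oracle_small_case(self):
        n = 20
        atoms = _helix_atoms(n)
        ref = toy_model({"A": [(i + 1, "ALA", {"CA": tuple(a["CA"])})
                               for i, a in enumerate(atoms)]}, model_id="ref")
        rng = np.random.default_rng(42)
        mod = toy_model({"A": [(i + 1, "ALA",
                                {"CA": tuple(np.asarray(a["CA"]) + rng.normal(0, 2.0, 3))})
                               for i, a in enumerate(atoms)]}, model_id="mod")
        tm = compute_tm(mod, ref)

        # oracle: best single Kabsch fit over 1e4 random residue subsets
        m_ca = np.array([r.atoms["CA"] for r in mod.chains[0].residues])
        r_ca = np.array([r.atoms["CA"] for r in ref.chains[0].residues])
        d0 = max(1.24 * (n - 15) ** (1 / 3) - 1.8, 0.5)
        best = 0.0
        for _ in range(10_000):
            k = int(rng.integers(4, n + 1))
            sel = rng.choice(n, size=k, replace=False)
            rot, trans, _ = kabsch_superpose(r_ca[sel], m_ca[sel])
            d = np.linalg.norm(m_ca @ rot.T + trans - r_ca, axis=1)
            best = max(best, float(np.sum(1 / (1 + (d / d0) ** 2)) / n))
        # every score the search reports is evaluated from an actual rigid
        # transform, so it cannot exceed the true optimum; the oracle is a
        # lower bound on that optimum.  The search must not trail it.
        assert tm >= best - 0.02
        assert tm <= 1.0

    def test_too_few_residues_rejected(self):
        m = toy_model({"A": [(i + 1, "ALA", {"CA": (3.8 * i, 0, 0)}) for i in range(5)]})
        with pytest.raises(Exception):
            compute_tm(m, m)


class TestGlobalInvariances:
    def test_rigid_motion_leaves_all_scores_unchanged(self, hetero_native, hetero_decoys):
        d = hetero_decoys[4]
        base = compute_pairwise_scores(d, hetero_native)
        rot = rotation_z(73.0) @ np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], float)
        moved = rigid_transform(d, rot, np.array([11.0, -3.0, 7.0]), model_id=d.model_id + "_mv")
        after = compute_pairwise_scores(moved, hetero_native)
        for name in ("oligo_lddt", "dockq", "fnat", "irms", "lrms", "qs",
                     "qs_official", "ics", "ips", "tm"):
            assert getattr(after, name) == pytest.approx(getattr(base, name), abs=1e-9), name

    def test_noise_degrades_every_bounded_metric(self, hetero_native):
        # mean over 50 replicates per quality rung.  All structural metrics
        # are non-increasing tier by tier.  fnat is the exception: around
        # sigma 0.5-2 A the minimum over the ~25 atom pairs of a residue pair
        # dips below the 5 A cutoff more often as spread grows, so its
        # expectation plateaus before collapsing; for fnat only the
        # end-to-end degradation is asserted.
        from assemblyqa.decoys import DEFAULT_LADDER
        from dataclasses import replace

        means = {k: [] for k in ("oligo_lddt", "dockq", "fnat", "qs", "qs_official",
                                 "ics", "ips", "tm")}
        for tier in DEFAULT_LADDER:
            spec = DecoyEnsembleSpec(n_chains=2, chain_lengths=(24, 20),
                                     stoichiometry="hetero", n_decoys=50, seed=12,
                                     noise_ladder=(replace(tier, fraction=1.0),))
            decoys = make_decoys(hetero_native, spec)
            vals = {k: [] for k in means}
            for d in decoys:
                s = compute_pairwise_scores(d, hetero_native)
                for k in means:
                    vals[k].append(getattr(s, k))
            for k in means:
                means[k].append(float(np.mean(vals[k])))
        for k, series in means.items():
            if k == "fnat":
                assert series[0] == 1.0 and series[-1] < series[0] - 0.1, series
            else:
                assert all(a >= b - 1e-12 for a, b in zip(series, series[1:])), (k, series)

    def test_all_bounded_scores_within_unit_interval(self, hetero_native, hetero_decoys):
        for d in hetero_decoys:
            s = compute_pairwise_scores(d, hetero_native)
            for name in ("oligo_lddt", "dockq", "fnat", "qs", "qs_official",
                         "ics", "ips", "tm"):
                v = getattr(s, name)
                assert 0.0 <= v <= 1.0, (name, v)
            assert s.irms >= 0 and s.lrms >= 0


def test_metric_params_validation():
    with pytest.raises(ValueError):
        MetricParams(qs_plateau=12.0, qs_max=5.0)
    with pytest.raises(ValueError):
        MetricParams(lddt_thresholds=(4.0, 1.0))
    with pytest.raises(ValueError):
        MetricParams(clash_cutoff=-1.0)
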