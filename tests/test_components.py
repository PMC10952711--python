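"""Jury, ModFOLDIA, CDA and voromqa component scorers."""

import numpy as np
import pytest

from assemblyqa.components import (
    AdapterError,
    JuryUndefinedError,
    ReferenceSet,
    cda_score,
    jury_score,
    modfoldia_residue_scores,
    voromqa_score,
)
from assemblyqa.metrics import compute_oligo_lddt
from conftest import toy_model


def copies(model, n, prefix="copy"):
    import copy

    out = []
    for k in range(n):
        c = copy.deepcopy(model)
        c.__dict__.pop("_cache", None)
        c.model_id = f"{prefix}{k}"
        out.append(c)
    return out


class TestJury:
    def test_identical_population_scores_one(self, homo_native):
        refs = ReferenceSet(copies(homo_native, 3), origin="population")
        model = copies(homo_native, 1, "probe")[0]
        for metric in ("dockq", "qs_weighted", "qs_official", "oligo_lddt"):
            assert jury_score(model, refs, metric).global_value == 1.0

    def test_single_reference_equals_pairwise(self, hetero_native, hetero_decoys):
        d = hetero_decoys[5]
        refs = ReferenceSet([hetero_native], origin="external-reference")
        jury = jury_score(d, refs, "oligo_lddt")
        assert jury.global_value == pytest.approx(
            compute_oligo_lddt(d, hetero_native), abs=1e-12)
        assert jury.method_name == "lDDTOfficialJury"

    def test_mean_over_references(self, hetero_native, hetero_decoys):
        refs = ReferenceSet([hetero_native, hetero_decoys[8]],
                            origin="external-reference")
        d = hetero_decoys[2]
        expected = np.mean([compute_oligo_lddt(d, hetero_native),
                            compute_oligo_lddt(d, hetero_decoys[8])])
        assert jury_score(d, refs, "oligo_lddt").global_value == pytest.approx(
            expected, abs=1e-12)

    def test_self_excluded(self, hetero_decoys):
        d = hetero_decoys[0]
        refs = ReferenceSet([d, hetero_decoys[1]], origin="population")
        # self comparison would be 1.0 and inflate the mean
        expected = compute_oligo_lddt(d, hetero_decoys[1])
        assert jury_score(d, refs, "oligo_lddt").global_value == pytest.approx(
            expected, abs=1e-12)

    def test_all_undefined_raises(self, hetero_native):
        # contactless references make DockQ undefined for every pair
        apart = copies(hetero_native, 2, "apart")
        for m in apart:
            for res in m.chains[1].residues:
                for k in res.atoms:
                    res.atoms[k] = res.atoms[k] + np.array([500.0, 0.0, 0.0])
        refs = ReferenceSet(apart, origin="external-reference")
        with pytest.raises(JuryUndefinedError):
            jury_score(hetero_native, refs, "dockq")

    def test_unknown_metric_rejected(self, hetero_native):
        refs = ReferenceSet([hetero_native])
        with pytest.raises(ValueError):
            jury_score(hetero_native, refs, "gdt_ts")


def contact_toy(partner_y):
    """Chains A, B of two residues; A1 contacts B1 when partner_y <= 5."""
    return toy_model({
        "A": [(1, "ALA", {"CA": (0, 0, 0)}), (2, "TRP", {"CA": (0, 0, 40)})],
        "B": [(1, "PHE", {"CA": (0, partner_y, 0)}), (2, "LYS", {"CA": (0, partner_y, 80)})],
    })


class TestModfoldia:
    def test_agreeing_references_score_one(self):
        model = contact_toy(4.0)
        model.model_id = "m"
        refs = ReferenceSet([contact_toy(4.0), contact_toy(4.5)],
                            origin="external-reference")
        cs = modfoldia_residue_scores(model, refs)
        # residues A1 and B1 share their single partner with every reference
        assert cs.per_residue[0] == pytest.approx(1.0)
        assert cs.global_value == pytest.approx(1.0)

    def test_half_agreement(self):
        # model: A1-B1 contact; ref1 agrees, ref2 has A1 contacting B2 instead
        model = contact_toy(4.0)
        ref2 = toy_model({
            "A": [(1, "ALA", {"CA": (0, 0, 0)}), (2, "TRP", {"CA": (0, 0, 40)})],
            "B": [(1, "PHE", {"CA": (0, 50, 0)}), (2, "LYS", {"CA": (0, 4, 0)})],
        }, model_id="ref2")
        refs = ReferenceSet([contact_toy(4.0), ref2], origin="external-reference")
        cs = modfoldia_residue_scores(model, refs)
        # A1: Jaccard 1 with ref1, 0 with ref2 -> 0.5
        assert cs.per_residue[0] == pytest.approx(0.5)

    def test_contactless_residue_scores_zero(self):
        model = contact_toy(4.0)
        cs = modfoldia_residue_scores(
            model, ReferenceSet([contact_toy(4.0)], origin="external-reference"))
        # A2/B2 are 40 A from everything
        assert cs.per_residue[1] == 0.0

    def test_reference_order_irrelevant(self, hetero_native, hetero_decoys):
        model = hetero_decoys[3]
        a = modfoldia_residue_scores(
            model, ReferenceSet(list(hetero_decoys[4:8]), origin="external-reference"))
        b = modfoldia_residue_scores(
            model, ReferenceSet(list(hetero_decoys[7:3:-1]), origin="external-reference"))
        assert a.per_residue == pytest.approx(b.per_residue, abs=1e-12)

    def test_duplicate_reference_pulls_towards_it(self, hetero_native, hetero_decoys):
        model = hetero_decoys[9]
        r1, r2 = hetero_decoys[1], hetero_decoys[6]
        base = modfoldia_residue_scores(
            model, ReferenceSet([r1, r2], origin="external-reference"))
        doubled = modfoldia_residue_scores(
            model, ReferenceSet([r1, r2, r2], origin="external-reference"))
        only_r2 = modfoldia_residue_scores(
            model, ReferenceSet([r2], origin="external-reference"))
        for b, d, t in zip(base.per_residue, doubled.per_residue, only_r2.per_residue):
            # doubling r2 moves the mean towards r2's agreement
            assert (d - b) * (t - b) >= -1e-12


class TestCda:
    def test_model_equal_to_single_reference(self, hetero_native):
        refs = ReferenceSet(copies(hetero_native, 1), origin="external-reference")
        assert cda_score(hetero_native, refs).global_value == pytest.approx(1.0)

    def test_single_contact_hand_case(self):
        def pair(dist, mid):
            return toy_model({
                "A": [(1, "ALA", {"CA": (0, 0, 0), "CB": (0, 0, 0)})],
                "B": [(1, "PHE", {"CA": (dist, 0, 0), "CB": (dist, 0, 0)})],
            }, model_id=mid)

        refs = ReferenceSet([pair(8.0, "r1")], origin="external-reference")
        # |8.9 - 8.0| = 0.9 -> passes 1/2/4, fails 0.5 -> 0.75
        assert cda_score(pair(8.9, "m"), refs).global_value == pytest.approx(0.75)
        # stretched far beyond every threshold -> 0
        assert cda_score(pair(20.0, "m2"), refs).global_value == 0.0


class TestVoromqa:
    def test_separated_chains_zero(self, hetero_native):
        apart = copies(hetero_native, 1, "apart")[0]
        for res in apart.chains[1].residues:
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + np.array([500.0, 0.0, 0.0])
        assert voromqa_score(apart).global_value == 0.0

    def test_formula_against_brute_force_counts(self, hetero_decoys):
        model = hetero_decoys[7]
        cs = voromqa_score(model)
        # brute-force C and X
        res = [(c.chain_id, i, r) for c in model.chains for i, r in enumerate(c.residues)]
        cb = {}
        for cid, i, r in res:
            at = r.atoms.get("CB", r.atoms.get("CA"))
            cb[(cid, i)] = at
        c_count = 0
        for a in range(len(res)):
            for b in range(a + 1, len(res)):
                (c1, i1, r1), (c2, i2, r2) = res[a], res[b]
                if c1 == c2:
                    continue
                if np.linalg.norm(cb[(c1, i1)] - cb[(c2, i2)]) <= 8.0:
                    c_count += 1
        x_count = 0
        for a in range(len(res)):
            for b in range(a + 1, len(res)):
                (c1, i1, r1), (c2, i2, r2) = res[a], res[b]
                if c1 == c2 and abs(i1 - i2) <= 1:
                    continue
                for p in r1.atoms.values():
                    for q in r2.atoms.values():
                        if np.linalg.norm(p - q) < 2.2:
                            x_count += 1
        assert cs.global_value == pytest.approx(
            c_count / (c_count + 4 * x_count + 10), abs=1e-12)

    def test_rigid_motion_invariant(self, hetero_native):
        from test_metrics import rigid_transform, rotation_z

        moved = rigid_transform(hetero_native, rotation_z(33.0), np.array([4.0, 5, 6]))
        assert voromqa_score(moved).global_value == pytest.approx(
            voromqa_score(hetero_native).global_value, abs=1e-12)

    def test_failing_external_tool_raises(self, hetero_native):
        with pytest.raises(AdapterError):
            voromqa_score(hetero_native, {"command": "false {model}"})

    def test_external_tool_output_parsed(self, hetero_native, tmp_path):
        script = tmp_path / "fake_voromqa.sh"
        script.write_text("#!/bin/sh\necho '{\"global\": 0.42, \"per_residue\": [0.1, 0.9]}'\n")
        script.chmod(0o755)
        cs = voromqa_score(hetero_native, {"command": f"{script} {{model}}"})
        assert cs.global_value == pytest.approx(0.42)
        assert cs.per_residue == [0.1, 0.9]


def test_component_score_validation():
    from assemblyqa.components import ComponentScore

    with pytest.raises(ValueError):
        ComponentScore("DockQJury", 1.2)
    with pytest.raises(ValueError):
        ComponentScore("CDA", 0.5, per_residue=[0.5, -0.1])
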