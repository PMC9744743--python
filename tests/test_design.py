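"""Mutation design: tip projection, introductions, removals, ranking,
verification, and the constraint guarantees."""

import numpy as np
import pytest

import hsgraft as hg
from hsgraft.design import (
    DesignConstraints,
    MutationProposal,
    project_mutant_tip,
    propose_introductions,
    propose_removals,
    rank_proposals,
)
from hsgraft.errors import CannotProjectError, ParameterError
from hsgraft.structure import MaskRange, MaskRanges, ResidueRecord


def make_fixture(seed=11, cand="S", buried=False, masked=False):
    spec = hg.FixtureSpec(
        n_residues=30,
        planted_pairs=[hg.PlantedPair("K", "K", 6.0)],
        planted_candidate=hg.PlantedCandidate(cand, buried=buried),
        seed=seed,
    )
    model, truth = hg.generate_fixture(spec)
    surface = hg.surface_profile(model)
    masks = MaskRanges(
        [MaskRange("A", truth["candidate"]["position"], truth["candidate"]["position"], "cdr")]
        if masked
        else []
    )
    return model, truth, surface, DesignConstraints(masks=masks)


class TestProjectMutantTip:
    def test_unit_vector_scaling(self):
        res = ResidueRecord(
            "A", 1, "S",
            {"CA": np.zeros(3), "CB": np.array([1.0, 0.0, 0.0])},
        )
        np.testing.assert_allclose(project_mutant_tip(res), [5.5, 0, 0])

    def test_degenerate_cb_rejected(self):
        res = ResidueRecord(
            "A", 1, "S", {"CA": np.zeros(3), "CB": np.zeros(3)}
        )
        with pytest.raises(CannotProjectError):
            project_mutant_tip(res)

    def test_missing_ca_rejected(self):
        res = ResidueRecord("A", 1, "S", {"CB": np.zeros(3)})
        with pytest.raises(CannotProjectError):
            project_mutant_tip(res)

    def test_glycine_gets_synthetic_cb(self):
        """Ideal backbone: the projected tip must land exactly 5.5 Å out,
        off the N–CA–C plane."""
        res = ResidueRecord(
            "A", 1, "G",
            {
                "N": np.array([-1.46, 0.0, 0.0]),
                "CA": np.zeros(3),
                "C": np.array([0.55, 1.4, 0.0]),
            },
        )
        tip = project_mutant_tip(res)
        assert np.linalg.norm(tip) == pytest.approx(5.5, abs=1e-6)
        assert abs(tip[2]) > 1.0  # out of the backbone plane


class TestIntroductions:
    def test_planted_candidate_top_ranked(self):
        model, truth, surface, constraints = make_fixture()
        proposals = propose_introductions(model, surface, constraints)
        assert proposals
        top = proposals[0]
        assert top.position == truth["candidate"]["position"]
        assert top.from_aa == "S" and top.to_aa == "K"
        assert len(top.anchors) == 2
        for _, d in top.anchors:
            assert 5.0 <= d <= 10.0

    def test_masked_candidate_skipped_with_audit(self):
        model, truth, surface, constraints = make_fixture(masked=True)
        proposals, audit = propose_introductions(
            model, surface, constraints, return_audit=True
        )
        cand = ("A", truth["candidate"]["position"])
        assert cand not in {( p.chain, p.position) for p in proposals}
        assert (cand, "masked") in audit

    def test_hydrophobic_candidate_skipped(self):
        model, truth, surface, constraints = make_fixture(cand="L")
        proposals = propose_introductions(model, surface, constraints)
        assert truth["candidate"]["position"] not in {
            p.position for p in proposals
        }

    def test_buried_candidate_skipped(self):
        model, truth, surface, constraints = make_fixture(buried=True)
        proposals = propose_introductions(model, surface, constraints)
        assert truth["candidate"]["position"] not in {
            p.position for p in proposals
        }

    def test_proline_site_allowed_but_flagged(self):
        model, truth, surface, constraints = make_fixture(cand="P")
        proposals = propose_introductions(model, surface, constraints)
        top = proposals[0]
        assert top.position == truth["candidate"]["position"]
        assert "proline-site" in top.flags

    def test_no_proposal_violates_constraints_randomized(self):
        """Property: across random fixtures no proposal is masked, buried,
        hydrophobic or basic."""
        for seed in range(25):
            spec = hg.FixtureSpec(
                n_residues=24,
                planted_pairs=[hg.PlantedPair("K", "R", 5.5 + (seed % 4))],
                planted_candidate=hg.PlantedCandidate("S"),
                masked_ranges=[MaskRange("A", 1, 5, "m")],
                seed=seed,
            )
            model, _ = hg.generate_fixture(spec)
            surface = hg.surface_profile(model)
            constraints = DesignConstraints(
                masks=MaskRanges(list(spec.masked_ranges))
            )
            for p in propose_introductions(model, surface, constraints):
                assert not constraints.masks.covers(p.chain, p.position)
                assert p.from_aa not in constraints.forbidden_from_aas
                assert p.from_aa not in "RKH"
                assert surface[(p.chain, p.position)].exposed


class TestRanking:
    def _proposal(self, pos, score):
        return MutationProposal("A", pos, "S", "K", "introduce", score=score)

    def test_more_anchors_rank_higher(self):
        a = self._proposal(10, 2.1)
        b = self._proposal(5, 1.1)
        assert rank_proposals([b, a])[0] is a

    def test_tie_broken_by_position(self):
        a, b = self._proposal(176, 1.5), self._proposal(75, 1.5)
        assert [p.position for p in rank_proposals([a, b])] == [75, 176]

    def test_empty(self):
        assert rank_proposals([]) == []


class TestRemovals:
    def test_per_site_proposes_every_unmasked_member(self, mimic):
        model, truth, surface = mimic
        clusters = hg.find_spatial_clusters(model, surface)
        masks = MaskRanges([MaskRange("A", 239, 239, "keep")])
        proposals = propose_removals(
            model, [], clusters, DesignConstraints(masks=masks), mode="per_site"
        )
        assert [p.notation for p in proposals] == ["K42Q", "K43Q"]

    def test_minimal_set_motif_with_exclusion(self, mimic, mimic_pattern):
        """With the shared anchor excluded, both remaining basics must go:
        leaving either one keeps a binding-competent basic pair."""
        model, truth, surface = mimic
        hits = hg.scan_linear_motifs({"A": model.sequence("A")}, mimic_pattern)
        masks = MaskRanges([MaskRange("A", 239, 239, "keep")])
        proposals = propose_removals(
            model,
            hits,
            [],
            DesignConstraints(masks=masks),
            mode="minimal_set",
            surface=surface,
            patterns=mimic_pattern,
        )
        assert [p.notation for p in proposals] == ["K243Q", "R244Q"]

    def test_minimal_set_unconstrained_is_smaller(self, mimic, mimic_pattern):
        """Without the exclusion one mutation can break every pair."""
        model, _, surface = mimic
        hits = hg.scan_linear_motifs({"A": model.sequence("A")}, mimic_pattern)
        proposals = propose_removals(
            model,
            hits,
            [],
            DesignConstraints(),
            mode="minimal_set",
            surface=surface,
            patterns=mimic_pattern,
        )
        assert len(proposals) == 2  # 3 basics, ≤1 may remain

    def test_minimal_set_self_verifies(self, mimic, mimic_pattern):
        model, _, surface = mimic
        hits = hg.scan_linear_motifs({"A": model.sequence("A")}, mimic_pattern)
        clusters = hg.find_spatial_clusters(model, surface)
        constraints = DesignConstraints(
            masks=MaskRanges([MaskRange("A", 239, 239, "keep")])
        )
        proposals = propose_removals(
            model, hits, clusters, constraints,
            mode="minimal_set", surface=surface, patterns=mimic_pattern,
        )
        mutated = hg.apply_proposals(model, proposals)
        new_hits = hg.scan_linear_motifs(
            {"A": mutated.sequence("A")}, mimic_pattern
        )
        targeted = {p for h in hits for p in h.basic_positions}
        assert not any(
            set(h.basic_positions) & targeted for h in new_hits
        )
        new_clusters = hg.find_spatial_clusters(mutated, surface)
        assert not any(
            {n for _, n in c.member_keys} & {42, 43, 239} for c in new_clusters
        )

    def test_fully_masked_site_unresolvable(self, mimic, mimic_pattern):
        model, _, surface = mimic
        hits = hg.scan_linear_motifs({"A": model.sequence("A")}, mimic_pattern)
        masks = MaskRanges([MaskRange("A", 230, 250, "all")])
        proposals, unresolvable = propose_removals(
            model, hits, [], DesignConstraints(masks=masks),
            mode="per_site", return_audit=True,
        )
        assert proposals == [] and len(unresolvable) == 1

    def test_empty_site_list_rejected(self, mimic):
        model, _, _ = mimic
        with pytest.raises(ParameterError):
            propose_removals(model, [], [], DesignConstraints())


class TestApplyRevert:
    def test_apply_then_revert_restores_sequence(self, mimic):
        model, _, surface = mimic
        clusters = hg.find_spatial_clusters(model, surface)
        proposals = propose_removals(
            model, [], clusters, DesignConstraints(), mode="per_site"
        )
        original = model.sequence("A")
        mutated = hg.apply_proposals(model, proposals)
        assert mutated.sequence("A") != original
        back = hg.revert_proposals(mutated, proposals)
        assert back.sequence("A") == original

    def test_charge_delta_crosscheck(self, planted_fixture):
        """+1 per introduced Lys, −1 per removed Lys, via the charge module."""
        model, truth = planted_fixture
        surface = hg.surface_profile(model)
        intro = propose_introductions(model, surface, DesignConstraints())[:1]
        assert hg.mutation_charge_delta(
            [p.notation for p in intro]
        ) == pytest.approx(1.0, abs=0.01)
        clusters = hg.find_spatial_clusters(model, surface)
        removals = propose_removals(
            model, [], clusters, DesignConstraints(), mode="per_site"
        )
        assert hg.mutation_charge_delta(
            [p.notation for p in removals]
        ) == pytest.approx(-1.0 * len(removals), abs=0.01)


class TestVerifyDesign:
    def test_introduction_creates_cluster(self, planted_fixture):
        model, truth = planted_fixture
        surface = hg.surface_profile(model)
        proposals = propose_introductions(model, surface, DesignConstraints())[:1]
        report = hg.verify_design(model, surface, proposals)
        assert report.ok
        assert report.entries[0]["verified"]
        assert report.net_charge_delta == pytest.approx(1.0, abs=0.01)

    def test_removal_clears_sites(self, mimic, mimic_pattern):
        model, _, surface = mimic
        hits = hg.scan_linear_motifs({"A": model.sequence("A")}, mimic_pattern)
        clusters = hg.find_spatial_clusters(model, surface)
        constraints = DesignConstraints(
            masks=MaskRanges([MaskRange("A", 239, 239, "keep")])
        )
        per_site = propose_removals(
            model, [], clusters, constraints, mode="per_site"
        )
        minimal = propose_removals(
            model, hits, [], constraints,
            mode="minimal_set", surface=surface, patterns=mimic_pattern,
        )
        report = hg.verify_design(
            model, surface, per_site + minimal, constraints, mimic_pattern
        )
        assert report.ok
        assert report.net_charge_delta == pytest.approx(-4.0, abs=0.01)

    def test_his_only_anchors_unverified_without_histidine(self):
        """An introduction anchored purely by His fails verification when
        His is dropped from the basic alphabet."""
        spec = hg.FixtureSpec(
            n_residues=30,
            planted_pairs=[hg.PlantedPair("H", "H", 6.0)],
            planted_candidate=hg.PlantedCandidate("S"),
            seed=13,
        )
        model, truth = hg.generate_fixture(spec)
        surface = hg.surface_profile(model)
        proposals = propose_introductions(model, surface, DesignConstraints())
        assert proposals and proposals[0].position == truth["candidate"]["position"]
        no_his = DesignConstraints(b_alphabet=frozenset("RK"))
        report = hg.verify_design(model, surface, proposals, no_his)
        assert not report.ok

    def test_constraint_validation(self):
        with pytest.raises(ParameterError):
            DesignConstraints(introduce_to_aa="S")
        with pytest.raises(ParameterError):
            DesignConstraints(removal_to_aa="K")
        with pytest.raises(ParameterError):
            DesignConstraints(removal_to_aa="E")
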