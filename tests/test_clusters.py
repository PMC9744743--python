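"""Spatial cluster detection vs a brute-force all-pairs oracle."""

import numpy as np
import pytest

import hsgraft as hg
from hsgraft.clusters import (
    DistanceBands,
    charged_group_centroid,
    find_completion_targets,
    find_spatial_clusters,
)
from hsgraft.errors import DomainError, ParameterError
from hsgraft.geometry import rotation_matrix
from hsgraft.structure import ResidueRecord, StructureModel
from hsgraft.surface import ResidueSurface, SurfaceProfile


def all_exposed_profile(model):
    """Stub profile marking every residue exposed (isolates cluster logic
    from the SASA engine)."""
    residues = {}
    for res in model.residues():
        residues[(res.chain_id, res.auth_seq_num)] = ResidueSurface(
            1.0, 100.0, True, None, True
        )
    return SurfaceProfile(residues, 0.2)


def model_of_lysines(points, aas=None, chain="A"):
    records = []
    for i, p in enumerate(points):
        aa = (aas or "K" * len(points))[i]
        tip_atom = {"K": "NZ", "R": "NH1", "H": "NE2"}.get(aa, "CB")
        records.append(
            ResidueRecord(
                chain,
                i + 1,
                aa,
                {
                    "CA": np.asarray(p, dtype=float) + [0, -2.0, 0],
                    tip_atom: np.asarray(p, dtype=float),
                },
            )
        )
    return StructureModel({chain: records})


def oracle_components(points, bands):
    """Independent oracle: explicit all-pairs edges + DFS components."""
    n = len(points)
    adj = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(np.asarray(points[i]) - points[j]))
            if bands.classify(d) is not None:
                adj[i].append(j)
                adj[j].append(i)
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v])
        seen |= comp
        if len(comp) >= 2:
            comps.append(frozenset(comp))
    return set(comps)


class TestChargedGroupCentroid:
    def test_lysine_nz(self):
        res = ResidueRecord("A", 1, "K", {"NZ": np.array([1.0, 2.0, 3.0])})
        xyz, flag = charged_group_centroid(res)
        np.testing.assert_allclose(xyz, [1, 2, 3])
        assert flag is None

    def test_arginine_guanidinium_mean(self):
        res = ResidueRecord(
            "A",
            1,
            "R",
            {
                "NH1": np.array([0.0, 0.0, 0.0]),
                "NH2": np.array([2.0, 0.0, 0.0]),
                "NE": np.array([1.0, 3.0, 0.0]),
            },
        )
        xyz, _ = charged_group_centroid(res)
        np.testing.assert_allclose(xyz, [1.0, 1.0, 0.0])

    def test_fallback_cb_flagged(self):
        res = ResidueRecord("A", 1, "K", {"CB": np.array([5.0, 5.0, 5.0])})
        xyz, flag = charged_group_centroid(res)
        np.testing.assert_allclose(xyz, [5, 5, 5])
        assert flag == "fallback-CB"

    def test_non_basic_rejected(self):
        res = ResidueRecord("A", 1, "S", {"CA": np.zeros(3)})
        with pytest.raises(DomainError):
            charged_group_centroid(res)


class TestBands:
    def test_classify(self):
        bands = DistanceBands((5, 10), (18, 22), use_long=True)
        assert bands.classify(7.0) == "short"
        assert bands.classify(20.0) == "long"
        assert bands.classify(12.0) is None
        assert bands.for_design().classify(20.0) is None

    def test_invalid_bands_rejected(self):
        with pytest.raises(ParameterError):
            DistanceBands((10, 5))
        with pytest.raises(ParameterError):
            DistanceBands((5, 10), (9, 22), use_long=True)


class TestFindClusters:
    def test_equilateral_triangle_complete(self):
        s = 7.0
        pts = [[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]]
        model = model_of_lysines(pts)
        clusters = find_spatial_clusters(model, all_exposed_profile(model))
        assert len(clusters) == 1
        assert clusters[0].size == 3 and clusters[0].complete
        for _, _, d, band in clusters[0].pair_distances:
            assert band == "short" and d == pytest.approx(7.0)

    def test_out_of_band_pair_no_cluster(self):
        model = model_of_lysines([[0, 0, 0], [12, 0, 0]])
        assert find_spatial_clusters(model, all_exposed_profile(model)) == []

    def test_pair_is_incomplete_cluster(self):
        model = model_of_lysines([[0, 0, 0], [6, 0, 0]])
        clusters = find_spatial_clusters(model, all_exposed_profile(model))
        assert len(clusters) == 1
        assert clusters[0].size == 2 and not clusters[0].complete

    def test_adjacent_pair_annotation(self):
        model = model_of_lysines([[0, 0, 0], [6, 0, 0]])
        clusters = find_spatial_clusters(model, all_exposed_profile(model))
        assert clusters[0].adjacent_pairs == [(("A", 1), ("A", 2))]

    def test_no_basics_is_empty(self):
        model = model_of_lysines([[0, 0, 0], [6, 0, 0]], aas="SS")
        assert find_spatial_clusters(model, all_exposed_profile(model)) == []

    def test_buried_basics_excluded(self):
        model = model_of_lysines([[0, 0, 0], [6, 0, 0], [3, 6, 0]])
        profile = all_exposed_profile(model)
        profile.residues[("A", 3)] = ResidueSurface(0.05, 5.0, True, None, False)
        clusters = find_spatial_clusters(model, profile)
        assert clusters[0].member_keys == {("A", 1), ("A", 2)}

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 50))
        pts = rng.uniform(0, 40, size=(n, 3))
        bands = DistanceBands((5, 10), (18, 22), use_long=bool(trial % 2))
        model = model_of_lysines(pts)
        clusters = find_spatial_clusters(
            model, all_exposed_profile(model), bands
        )
        got = {
            frozenset(num - 1 for _, num in c.member_keys) for c in clusters
        }
        assert got == oracle_components(pts, bands)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 30, size=(20, 3))
        rot = rotation_matrix([0.3, 1.0, -0.2], 2.0)
        moved = pts @ rot.T + np.array([5.0, -3.0, 9.0])
        m1, m2 = model_of_lysines(pts), model_of_lysines(moved)
        c1 = find_spatial_clusters(m1, all_exposed_profile(m1))
        c2 = find_spatial_clusters(m2, all_exposed_profile(m2))
        assert [c.member_keys for c in c1] == [c.member_keys for c in c2]

    def test_band_widening_monotone(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 30, size=(25, 3))
        model = model_of_lysines(pts)
        profile = all_exposed_profile(model)
        narrow = find_spatial_clusters(model, profile, DistanceBands((5, 8), None, False))
        wide = find_spatial_clusters(model, profile, DistanceBands((4, 11), None, False))
        # every narrow-band cluster is contained in some wide-band cluster
        for c in narrow:
            assert any(c.member_keys <= w.member_keys for w in wide)

    def test_reported_distances_recompute_in_band(self, mimic):
        model, _, surface = mimic
        for cluster in find_spatial_clusters(model, surface):
            for (a, b, d, band) in cluster.pair_distances:
                ta, _ = charged_group_centroid(model.get(*a))
                tb, _ = charged_group_centroid(model.get(*b))
                again = float(np.linalg.norm(ta - tb))
                assert again == pytest.approx(d, abs=1e-9)
                assert DistanceBands().classify(again) == band


class TestCompletionTargets:
    def _fixture(self, cand_aa="S", bury=False):
        spec = hg.FixtureSpec(
            n_residues=30,
            planted_pairs=[hg.PlantedPair("K", "K", 6.0)],
            planted_candidate=hg.PlantedCandidate(cand_aa, buried=bury),
            seed=5,
        )
        model, truth = hg.generate_fixture(spec)
        return model, truth, hg.surface_profile(model)

    def test_planted_candidate_listed_with_two_anchors(self):
        model, truth, surface = self._fixture()
        targets = find_completion_targets(model, surface)
        keys = {k for k, _ in targets}
        cand = ("A", truth["candidate"]["position"])
        assert cand in keys
        anchors = dict(targets)[cand]
        assert len(anchors) == 2

    def test_buried_candidate_not_listed(self):
        model, truth, surface = self._fixture(bury=True)
        targets = find_completion_targets(model, surface)
        assert ("A", truth["candidate"]["position"]) not in {
            k for k, _ in targets
        }

    def test_single_anchor_reachable_with_min_anchors_one(self):
        """A lone basic anchor near a surface residue — the single-anchor
        graft shape — appears only when min_anchors is relaxed to 1."""
        pts = [[0.0, 0.0, 0.0]]
        model = model_of_lysines(pts)
        # add a serine whose projected tip lands ~7 Å from the anchor
        ca = np.array([12.5, 0.0, 0.0])
        cb = ca + 1.53 * np.array([-1.0, 0.0, 0.0])
        model.chains["A"].append(
            ResidueRecord("A", 2, "S", {"CA": ca, "CB": cb})
        )
        profile = all_exposed_profile(model)
        assert find_completion_targets(model, profile, min_anchors=2) == []
        targets = find_completion_targets(model, profile, min_anchors=1)
        assert [k for k, _ in targets] == [("A", 2)]
        ((_, anchors),) = targets
        assert anchors[0][1] == pytest.approx(7.0)
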