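"""Expression distance, spatial candidate search, local-search matching,
displacement fields and tallies — each checked against brute force."""

import numpy as np
import pytest

import crossatlas as ca
from crossatlas.atlas import ExpressionProfile
from crossatlas.errors import IntegrityError

GENES2 = ["gene1", "gene2"]


def make_profile(values, genes=GENES2, missing=None):
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.zeros(values.shape, dtype=bool)
    return ExpressionProfile(genes=list(genes), values=values, missing=missing)


class TestExpressionDistance:
    def test_identical_profiles_zero(self):
        p = make_profile([[0.1, 0.5], [0.3, 0.9]])
        assert ca.expression_distance(p, p) == 0.0

    def test_single_entry_difference(self):
        a = make_profile([[0.0, 0.0], [0.0, 0.0]])
        b = make_profile([[1.0, 0.0], [0.0, 0.0]])
        assert ca.expression_distance(a, b) == pytest.approx(1.0)

    def test_worked_example(self):
        a = make_profile([[0.1, 0.5, 0.9], [0.0, 0.2, 0.4]])
        b = make_profile([[0.1, 0.5, 0.8], [0.0, 0.3, 0.4]])
        assert ca.expression_distance(a, b) == pytest.approx(0.02)
        dec = ca.distance_decomposition(a, b)
        assert dec.set_index("gene")["score"].to_dict() == pytest.approx(
            {"gene1": 0.01, "gene2": 0.01}
        )

    def test_symmetry_and_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(5)]
        for _ in range(100):
            va, vb = rng.uniform(0, 1, (2, 5, 4))
            a, b = make_profile(va, genes), make_profile(vb, genes)
            brute = sum(
                (va[g, t] - vb[g, t]) ** 2 for g in range(5) for t in range(4)
            )
            assert ca.expression_distance(a, b) == pytest.approx(brute, abs=1e-12)
            assert ca.expression_distance(b, a) == pytest.approx(
                ca.expression_distance(a, b), abs=1e-15
            )

    def test_additivity_over_disjoint_subsets(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(6)]
        va, vb = rng.uniform(0, 1, (2, 6, 3))
        a, b = make_profile(va, genes), make_profile(vb, genes)
        full = ca.expression_distance(a, b, ca.GeneSubset(genes))
        part1 = ca.expression_distance(a, b, ca.GeneSubset(genes[:3]))
        part2 = ca.expression_distance(a, b, ca.GeneSubset(genes[3:]))
        assert part1 + part2 == pytest.approx(full, abs=1e-12)

    def test_masked_entries_dropped_from_both(self):
        missing = np.zeros((2, 2), dtype=bool)
        missing[0, 1] = True
        a = make_profile([[0.2, 99.0], [0.1, 0.1]], missing=missing)
        b = make_profile([[0.2, 0.0], [0.1, 0.1]])
        assert ca.expression_distance(a, b) == 0.0

    def test_single_gene_decomposition_equals_total(self):
        a = make_profile([[0.3, 0.7]], genes=["eve"])
        b = make_profile([[0.1, 0.9]], genes=["eve"])
        dec = ca.distance_decomposition(a, b)
        assert dec["score"].sum() == pytest.approx(ca.expression_distance(a, b))

    def test_unnormalized_atlas_rejected(self, small_atlas):
        with pytest.raises(IntegrityError, match="normalized"):
            ca.match_all(small_atlas, small_atlas)


class TestSpatialKnn:
    def test_self_query_k1(self, small_normalized):
        cand = ca.spatial_knn(small_normalized, small_normalized, ca.MatchConfig(k=1, m=1))
        np.testing.assert_array_equal(cand[:, 0], np.arange(small_normalized.n_cells))

    def test_colinear_cells(self):
        from conftest import toy_atlas
        atlas = toy_atlas(n=3)
        atlas.positions[:, :, 0] = np.array([0.0, 1.0, 3.0])[:, None]
        atlas.positions[:, :, 1:] = 0.0
        cand = ca.spatial_knn(atlas, atlas, ca.MatchConfig(k=2, m=1))
        assert cand[0, 1] == 1  # nearest other cell to x=0 is x=1

    def test_k_too_large_rejected(self, small_normalized):
        with pytest.raises(ValueError, match="exceeds"):
            ca.spatial_knn(small_normalized, small_normalized,
                           ca.MatchConfig(k=small_normalized.n_cells + 1, m=1))

    def test_brute_force_oracle(self, null_pair):
        a, b, _ = null_pair
        cfg = ca.MatchConfig(k=12, m=5)
        cand = ca.spatial_knn(a, b, cfg)
        qpos, tpos = ca.align_atlases(a, b, cfg.resolve_cohort(a))
        rng = np.random.default_rng(0)
        for i in rng.choice(a.n_cells, 200, replace=False):
            d = np.linalg.norm(tpos - qpos[i], axis=1)
            expected = np.lexsort((np.arange(b.n_cells), d))[:12]
            np.testing.assert_array_equal(np.sort(cand[i]), np.sort(expected))


class TestMatchAll:
    def test_identical_atlases_identity_mapping(self, small_normalized):
        m = ca.match_all(small_normalized, small_normalized)
        np.testing.assert_array_equal(m.best_ids, m.query_ids)
        np.testing.assert_array_equal(m.best_scores, 0.0)

    def test_best_never_worse_than_nearest(self, null_pair):
        a, b, _ = null_pair
        m = ca.match_all(a, b)
        assert np.all(m.best_scores <= m.nearest_scores + 1e-15)
        assert m.best_scores.mean() <= m.nearest_scores.mean()

    def test_local_search_improves_on_shifted_pair(self):
        """With a true positional shift, local search strictly reduces the
        mean score versus the direct spatial mapping."""
        sa = ca.SpeciesSpec(label="A", n_nuclei=600, seed=31)
        sb = ca.SpeciesSpec(label="B", n_nuclei=600, seed=32)
        genes = [p.gene for p in ca.segmentation_network_patterns()]
        a, b, _ = ca.generate_species_pair(
            sa, sb, perturb_b=ca.PerturbationSpec.uniform_ap_shift(0.03, genes)
        )
        a, b = ca.normalize_atlas(a), ca.normalize_atlas(b)
        m = ca.match_all(a, b, ca.MatchConfig(genes=ca.GeneSubset.default_for(a)))
        assert m.best_scores.mean() < 0.75 * m.nearest_scores.mean()

    def test_many_to_one_allowed(self, null_pair):
        a, b, _ = null_pair
        m = ca.match_all(a, b)
        # more query cells than target cells forces shared best targets
        assert len(np.unique(m.best_ids)) < a.n_cells

    def test_scores_sorted_ascending(self, null_pair):
        a, b, _ = null_pair
        m = ca.match_all(a, b)
        assert np.all(np.diff(m.candidate_scores, axis=1) >= 0)


class TestDisplacement:
    def test_m1_endpoint_is_best_match(self, null_pair):
        a, b, _ = null_pair
        cfg = ca.MatchConfig(k=10, m=1)
        m = ca.match_all(a, b, cfg)
        disp = ca.displacement_field(m, a, b, cfg)
        qpos, tpos = ca.align_atlases(a, b, cfg.resolve_cohort(a))
        expected = tpos[m.best_ids] - qpos
        np.testing.assert_allclose(
            disp[["disp_x", "disp_y", "disp_z"]].to_numpy(), expected, atol=1e-12
        )

    def test_identical_atlases_zero_displacement(self, small_normalized):
        m = ca.match_all(small_normalized, small_normalized)
        disp = ca.displacement_field(m, small_normalized, small_normalized)
        np.testing.assert_allclose(disp["disp_len_scaled"], 0.0, atol=1e-12)

    def test_recovers_injected_ap_shift(self):
        delta = 0.05
        sa = ca.SpeciesSpec(label="A", n_nuclei=800, noise_sd=0.0, seed=41)
        sb = ca.SpeciesSpec(label="B", n_nuclei=800, noise_sd=0.0, seed=42)
        genes = [p.gene for p in ca.segmentation_network_patterns()]
        a, b, _ = ca.generate_species_pair(
            sa, sb, perturb_b=ca.PerturbationSpec.uniform_ap_shift(delta, genes)
        )
        a, b = ca.normalize_atlas(a), ca.normalize_atlas(b)
        cfg = ca.MatchConfig(genes=ca.GeneSubset.default_for(a))
        m = ca.match_all(a, b, cfg)
        disp = ca.displacement_field(m, a, b, cfg)
        pc = ca.cylindrical_projection(a, a.T)
        trunk = (pc.axial > 0.3) & (pc.axial < 0.85)
        spacing_scaled = ca.mean_internuclear_spacing(a, a.T) / a.egg_length
        err = abs(disp["disp_x"][trunk].mean() - delta)
        assert err < spacing_scaled / 2

    def test_zero_distance_candidates_get_equal_weight(self, small_normalized):
        cfg = ca.MatchConfig(k=5, m=3)
        m = ca.match_all(small_normalized, small_normalized, cfg)
        disp = ca.displacement_field(m, small_normalized, small_normalized, cfg)
        # self-comparison: only the zero-distance candidate (itself) weighted
        np.testing.assert_allclose(disp["disp_len_scaled"], 0.0, atol=1e-12)


class TestTally:
    def test_identity_m1_each_target_once(self, small_normalized):
        cfg = ca.MatchConfig(k=5, m=1)
        m = ca.match_all(small_normalized, small_normalized, cfg)
        counts, frac = ca.match_tally(m, small_normalized, cfg)
        np.testing.assert_array_equal(counts, 1)
        assert frac == 1.0

    def test_count_conservation(self, null_pair):
        a, b, _ = null_pair
        cfg = ca.MatchConfig(k=30, m=10)
        m = ca.match_all(a, b, cfg)
        counts, _ = ca.match_tally(m, b, cfg)
        assert counts.sum() == 10 * a.n_cells

    def test_null_pair_high_matched_fraction(self, null_pair):
        a, b, _ = null_pair
        m = ca.match_all(a, b, ca.MatchConfig(genes=ca.GeneSubset.default_for(a)))
        _, frac = ca.match_tally(m, b)
        assert frac >= 0.95
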