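import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from compositemap.merge import (
    MergeConfig,
    build_composite,
    build_linkage_group,
    fit_projection,
    fit_value,
    select_best_component,
    select_seed_map,
    spearman_rho,
    trim_ends,
)
from compositemap.model import CompositeLocus, MarkerLocus

from conftest import make_map


def brute_spearman(a, b):
    """Independent oracle: mean ranks + Pearson correlation from definition."""

    def ranks(x):
        x = np.asarray(x, dtype=float)
        r = np.empty(len(x))
        for i, v in enumerate(x):
            less = np.sum(x < v)
            equal = np.sum(x == v)
            r[i] = less + (equal + 1) / 2.0
        return r

    ra, rb = ranks(a), ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float(np.sum(ra * rb) / math.sqrt(np.sum(ra**2) * np.sum(rb**2)))


class TestSpearman:
    def test_same_order_is_one(self):
        assert spearman_rho([0, 5, 10], [2, 4, 9]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert spearman_rho([0, 5, 10], [9, 4, 2]) == pytest.approx(-1.0)

    def test_adjacent_swap_matches_rank_definition(self):
        a = [0.0, 2.0, 5.0, 7.0, 11.0, 14.0]
        b = [0.0, 2.0, 7.0, 5.0, 11.0, 14.0]  # one adjacent swap
        assert spearman_rho(a, b) == pytest.approx(brute_spearman(a, b), abs=1e-12)

    @pytest.mark.parametrize("a,b", [([1.0], [2.0]), ([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])])
    def test_undefined_cases(self, a, b):
        assert spearman_rho(a, b) is None

    @given(
        st.lists(
            st.floats(min_value=0, max_value=200, allow_nan=False), min_size=3, max_size=30
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_oracle_on_random_vectors(self, positions, rnd):
        b = positions[:]
        rnd.shuffle(b)
        result = spearman_rho(positions, b)
        if len(set(positions)) < 2:
            assert result is None
        else:
            assert result == pytest.approx(brute_spearman(positions, b), abs=1e-9)


class TestFitValue:
    def test_single_common_marker_scores_zero(self):
        assert fit_value(0.97, 1) == 0.0

    def test_log10_of_ten_anchors(self):
        assert fit_value(1.0, 10, log_base=10) == pytest.approx(1.0)

    def test_many_weak_anchors_beat_few_strong(self):
        # 0.80 x log10(100) = 1.600 > 0.99 x log10(5) = 0.692
        assert fit_value(0.80, 100) == pytest.approx(1.600, abs=1e-3)
        assert fit_value(0.99, 5) == pytest.approx(0.692, abs=1e-3)
        assert fit_value(0.80, 100) > fit_value(0.99, 5)

    def test_zero_common_markers_undefined(self):
        assert fit_value(0.9, 0) is None

    def test_uses_rho_magnitude(self):
        assert fit_value(-0.9, 10) == fit_value(0.9, 10)


class TestFitProjection:
    def test_identity_line(self):
        proj = fit_projection([0, 50, 100], [0, 50, 100])
        assert (proj.slope, proj.intercept) == (pytest.approx(1.0), pytest.approx(0.0))
        assert proj.residual_rmse == pytest.approx(0.0, abs=1e-12)

    def test_two_point_line(self):
        proj = fit_projection([10, 110], [0, 100])
        assert proj.slope == pytest.approx(1.0)
        assert proj.intercept == pytest.approx(10.0)

    def test_matches_normal_equations_oracle(self):
        pc = np.array([0.0, 10.0, 20.0])
        pi = np.array([0.0, 4.0, 12.0])
        # oracle: solve X^T X beta = X^T y directly
        X = np.column_stack([pi, np.ones(3)])
        m, c = np.linalg.solve(X.T @ X, X.T @ pc)
        proj = fit_projection(pc, pi)
        assert proj.slope == pytest.approx(m, abs=1e-9)
        assert proj.intercept == pytest.approx(c, abs=1e-9)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_projection([0, 10], [5, 5])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=150, allow_nan=False),
                st.floats(min_value=0, max_value=150, allow_nan=False),
            ),
            min_size=2,
            max_size=25,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_ols_property_on_random_anchors(self, pairs):
        pc = np.array([p[0] for p in pairs])
        pi = np.array([p[1] for p in pairs])
        if np.all(pi == pi[0]) or np.var(pi) == 0.0:
            with pytest.raises(ValueError, match="degenerate"):
                fit_projection(pc, pi)
            return
        proj = fit_projection(pc, pi)
        X = np.column_stack([pi, np.ones(len(pi))])
        beta, *_ = np.linalg.lstsq(X, pc, rcond=None)
        assert proj.slope == pytest.approx(beta[0], abs=1e-8)
        assert proj.intercept == pytest.approx(beta[1], abs=1e-8)


def as_candidates(*maps_lgs):
    return [(m.map_id, lg, m.linkage_groups[lg]) for m, lg in maps_lgs]


def seed_lg(pairs):
    return make_map("SEED", {"LG1": pairs}).linkage_groups["LG1"]


class TestSelectBestComponent:
    def building(self, pairs):
        return [CompositeLocus(n, "LG1", p, "DArT", {"SEED"}, 0) for n, p in pairs]

    def cand(self, map_id, pairs, order=0):
        from compositemap.merge import _Candidate

        loci = sorted(
            (MarkerLocus(n, "LG1", p) for n, p in pairs), key=lambda l: l.position
        )
        return _Candidate(map_id, "LG1", loci, order)

    def test_two_common_markers_ineligible(self):
        building = self.building([("a", 0.0), ("b", 10.0), ("c", 20.0)])
        cand = self.cand("M2", [("a", 0.0), ("b", 9.0)])
        assert select_best_component(building, [cand]) is None

    def test_low_rho_ineligible(self):
        building = self.building([(f"m{i}", float(i)) for i in range(10)])
        # order scrambled enough to push |rho| below 0.50
        cand = self.cand("M2", [("m0", 0), ("m5", 1), ("m2", 2), ("m7", 3), ("m4", 4),
                                ("m9", 5), ("m6", 6), ("m1", 7), ("m8", 8), ("m3", 9)])
        rho = spearman_rho(range(10), [0, 7, 2, 9, 4, 1, 6, 3, 8, 5])
        assert abs(rho) < 0.50
        assert select_best_component(building, [cand]) is None

    def test_fit_value_ranking_picks_many_anchor_candidate(self):
        building = self.building([(f"m{i}", float(i)) for i in range(100)] + [("x", 200.0)])
        # A: 5 anchors in perfect order; B: 100 anchors, rho ~ 0.8
        cand_a = self.cand("A", [(f"m{i}", float(i)) for i in range(5)], order=0)
        rng = np.random.default_rng(1)
        noisy = np.arange(100) + rng.normal(0, 25, 100)
        pairs_b = [(f"m{i}", float(noisy[i] - noisy.min())) for i in range(100)]
        cand_b = self.cand("B", pairs_b, order=1)
        rho_b = spearman_rho(np.arange(100), noisy)
        assert 0.5 < abs(rho_b) < 0.95
        assert fit_value(rho_b, 100) > fit_value(1.0, 5)
        cmp_, chosen = select_best_component(building, [cand_a, cand_b])
        assert chosen.map_id == "B"

    def test_selection_invariant_to_log_base(self):
        building = self.building([(f"m{i}", float(i)) for i in range(50)])
        cands = [
            self.cand("A", [(f"m{i}", float(i)) for i in range(0, 50, 10)], order=0),
            self.cand("B", [(f"m{i}", float(i)) for i in range(0, 50, 2)], order=1),
        ]
        pick10 = select_best_component(building, cands, log_base=10.0)
        pick_e = select_best_component(building, cands, log_base=math.e)
        assert pick10[1].map_id == pick_e[1].map_id


class TestBuildLinkageGroup:
    def test_no_eligible_candidates_returns_seed(self):
        seed = seed_lg([("a", 0.0), ("b", 10.0)])
        built, log = build_linkage_group("LG1", seed, [], "SEED")
        assert [(l.name, l.position) for l in built] == [("a", 0.0), ("b", 10.0)]
        assert log == []

    def test_single_round_interpolation_keeps_seed_fixed(self):
        seed = seed_lg([("a", 0.0), ("b", 10.0), ("c", 20.0)])
        m2 = make_map("M2", {"LG1": [("a", 0.0), ("x", 5.0), ("b", 10.0), ("c", 20.0)]})
        built, log = build_linkage_group("LG1", seed, as_candidates((m2, "LG1")), "SEED")
        positions = {l.name: l.position for l in built}
        assert positions == pytest.approx({"a": 0.0, "b": 10.0, "c": 20.0, "x": 5.0})
        assert len(log) == 1
        assert log[0].markers_added == 1 and log[0].markers_skipped == 3
        # shared markers gained provenance
        assert {l.name: l.support for l in built}["a"] == {"SEED", "M2"}

    def test_two_round_chaining_through_projected_markers(self):
        # M3 shares 3 markers with the building LG only after M2's round
        seed = seed_lg([("a", 0.0), ("b", 10.0), ("c", 20.0)])
        m2 = make_map("M2", {"LG1": [("a", 0.0), ("b", 10.0), ("c", 20.0), ("d", 30.0)]})
        m3 = make_map("M3", {"LG1": [("b", 0.0), ("c", 10.0), ("d", 20.0), ("e", 30.0)]})
        built, log = build_linkage_group(
            "LG1", seed, as_candidates((m2, "LG1"), (m3, "LG1")), "SEED"
        )
        positions = {l.name: l.position for l in built}
        assert positions == pytest.approx(
            {"a": 0.0, "b": 10.0, "c": 20.0, "d": 30.0, "e": 40.0}
        )
        assert [r.component_map_id for r in log] == ["M2", "M3"]
        assert log[1].n_common == 3  # b, c, d — d only exists via round 1

    def test_reversed_component_is_flipped_before_regression(self):
        seed = seed_lg([("a", 0.0), ("b", 10.0), ("c", 20.0)])
        m2 = make_map("M2", {"LG1": [("x", 0.0), ("c", 5.0), ("b", 15.0), ("a", 25.0)]})
        built, log = build_linkage_group("LG1", seed, as_candidates((m2, "LG1")), "SEED")
        positions = {l.name: l.position for l in built}
        assert log[0].orientation == "reversed"
        # flipped pi: a=0, b=10, c=20, x=25 -> identity line -> x at 25
        assert positions["x"] == pytest.approx(25.0)
        assert positions["a"] == pytest.approx(0.0)

    def test_monotone_projection_preserves_component_order(self):
        seed = seed_lg([(f"m{i}", 10.0 * i) for i in range(6)])
        extra = [(f"u{i}", 10.0 * i + 4.0) for i in range(6)]
        m2 = make_map("M2", {"LG1": [(f"m{i}", 5.0 * i) for i in range(6)]
                             + [(n, p / 2.0) for n, p in extra]})
        built, _ = build_linkage_group("LG1", seed, as_candidates((m2, "LG1")), "SEED")
        comp_order = [l.name for l in built if l.name.startswith("u")]
        comp_pos = {l.name: l.position for l in m2.linkage_groups["LG1"]}
        true_order = sorted(comp_order, key=lambda n: comp_pos[n])
        assert comp_order == true_order


class TestTrimEnds:
    def locus(self, name, pos, n_support):
        return CompositeLocus(name, "LG1", pos, "DArT", {f"M{i}" for i in range(n_support)}, 0)

    def test_distal_weakly_supported_marker_removed(self):
        loci = [self.locus("a", 0.0, 1), self.locus("b", 6.0, 2), self.locus("c", 10.0, 2)]
        kept, removed = trim_ends(loci)
        assert [l.name for l in removed] == ["a"]
        assert [l.position for l in kept] == pytest.approx([0.0, 4.0])

    def test_well_supported_distal_marker_retained(self):
        loci = [self.locus("a", 0.0, 3), self.locus("b", 6.0, 2), self.locus("c", 10.0, 2)]
        kept, removed = trim_ends(loci)
        assert removed == [] and len(kept) == 3

    def test_small_gap_retained(self):
        loci = [self.locus("a", 0.0, 1), self.locus("b", 4.9, 2), self.locus("c", 10.0, 2)]
        kept, removed = trim_ends(loci)
        assert removed == []

    def test_cascading_trim_from_both_ends(self):
        loci = [
            self.locus("a", 0.0, 1),
            self.locus("b", 5.0, 1),
            self.locus("c", 11.0, 2),
            self.locus("d", 15.0, 2),
            self.locus("e", 22.0, 1),
        ]
        kept, removed = trim_ends(loci)
        assert {l.name for l in removed} == {"a", "b", "e"}
        assert [l.position for l in kept] == pytest.approx([0.0, 4.0])

    def test_idempotent(self):
        loci = [
            self.locus("a", 0.0, 1),
            self.locus("b", 7.0, 2),
            self.locus("c", 12.0, 1),
            self.locus("d", 19.0, 1),
        ]
        once, _ = trim_ends(loci)
        twice, removed_again = trim_ends(once)
        assert removed_again == []
        assert [(l.name, l.position) for l in twice] == [(l.name, l.position) for l in once]


class TestBuildComposite:
    def test_requires_two_maps(self, toy_pair):
        m1, _ = toy_pair
        with pytest.raises(ValueError):
            build_composite([m1])

    def test_seed_selection_order(self):
        a = make_map("A", {"LG1": [("m1", 0.0), ("m2", 1.0)]}, family_size=100)
        b = make_map("B", {"LG1": [("m1", 0.0), ("m2", 1.0), ("m3", 2.0)]}, family_size=50)
        c = make_map("C", {"LG1": [("m1", 0.0), ("m2", 1.0)]}, family_size=100)
        assert select_seed_map([a, b, c]).map_id == "B"  # most markers wins
        assert select_seed_map([a, c]).map_id == "A"  # tie -> lexical id

    def test_identical_maps_give_seed_back(self):
        lgs = {"LG1": [(f"m{i}", 2.0 * i) for i in range(8)],
               "LG2": [(f"n{i}", 3.0 * i) for i in range(6)]}
        m1 = make_map("M1", lgs, family_size=500)
        m2 = make_map("M2", lgs, family_size=100)
        comp = build_composite([m1, m2])
        assert comp.seed_map_id == "M1"
        for lg in lgs:
            got = [(l.name, l.position) for l in comp.linkage_groups[lg]]
            want = [(l.name, l.position) for l in m1.linkage_groups[lg]]
            assert got == want
        # one merge round per LG adding nothing
        assert len(comp.merge_log) == 2
        assert all(r.markers_added == 0 for r in comp.merge_log)
        assert all(len(l.support) == 2 for l in comp.loci())

    def test_backbone_immutability_under_noise(self):
        from compositemap.synth import SynthConfig, generate_dataset

        cfg = SynthConfig(seed=11, n_lgs=3, markers_per_lg=120, n_component_maps=3,
                          retention=(0.8, 0.5, 0.4), length_scale=(1.0, 1.1, 0.95),
                          family_sizes=(500, 200, 150), multicopy_fraction=0.0,
                          redundant_pairs=0, n_discordant_lgs=0)
        maps, _, _ = generate_dataset(cfg)
        seed = select_seed_map(maps)
        comp = build_composite(maps, MergeConfig(trim_gap_cm=1e9))
        for lg, loci in comp.linkage_groups.items():
            comp_pos = {l.name: l.position for l in loci}
            seed_pos = {l.name: l.position for l in seed.linkage_groups[lg]}
            diffs = {n: comp_pos[n] - seed_pos[n] for n in seed_pos}
            # rigid translation only: all differences equal
            values = list(diffs.values())
            assert max(values) - min(values) < 1e-9
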