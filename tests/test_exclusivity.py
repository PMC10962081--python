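import numpy as np
import pytest
from helpers import make_table, mcf_bruteforce

from loopstate.clustering import mean_shift_cluster
from loopstate.exceptions import AnalysisError
from loopstate.exclusivity import (
    exclusivity_verdict,
    mark_connection,
    overlap_fraction,
)
from loopstate.synthetic_data import FibreSimConfig, simulate_fibre


def exclusive_fibre(seed=1, **kw):
    cfg = FibreSimConfig(
        n_rois=6, spacing_mean=300, spacing_sd=30, curvature=0.0, exclusivity=1.0,
        seed=seed, **kw,
    )
    return simulate_fibre(cfg), cfg


class TestOverlapFraction:
    def test_distant_points_give_zero(self, rng):
        pts = rng.normal(0, 10, size=(30, 2))
        cs = mean_shift_cluster(make_table(pts, "A"), "A")
        other = make_table(pts + [5000.0, 0.0], "B")
        assert overlap_fraction(cs, other, "B").median_fraction == 0.0

    def test_points_at_centres_give_one(self, rng):
        pts = rng.normal(0, 10, size=(30, 2))
        cs = mean_shift_cluster(make_table(pts, "A"), "A")
        other = make_table(np.tile(cs.clusters[0].centre, (5, 1)), "B")
        assert overlap_fraction(cs, other, "B").median_fraction == 1.0

    def test_fraction_counts_points_within_radius(self, rng):
        """20 other-mark points with exactly 3 inside the 50 nm radius -> 0.15."""
        pts = rng.normal(0, 10, size=(30, 2))
        cs = mean_shift_cluster(make_table(pts, "A"), "A")
        centre = cs.clusters[0].centre
        inside = centre + np.array([[10, 0], [0, -20], [30, 5]])
        outside = centre + np.column_stack(
            [np.linspace(200, 900, 17), np.zeros(17)]
        )
        other = make_table(np.vstack([inside, outside]), "B")
        result = overlap_fraction(cs, other, "B")
        assert result.median_fraction == pytest.approx(0.15)

    def test_empty_clusterset_is_undefined(self, rng):
        from loopstate.clustering import ClusteringParams, ClusterSet

        other = make_table(rng.normal(0, 10, (5, 2)), "B")
        with pytest.raises(AnalysisError):
            overlap_fraction(ClusterSet("A", [], ClusteringParams()), other, "B")

    def test_coherence_with_exclusive_simulation(self):
        """Zero constructed contamination implies near-zero measured overlap and a
        small-distance repulsion verdict."""
        (table, truth), cfg = exclusive_fibre(seed=8)
        cs = mean_shift_cluster(table, cfg.class_labels[0])
        ov = overlap_fraction(cs, table, cfg.class_labels[1])
        assert truth.true_overlap_fraction == 0.0
        assert ov.median_fraction < 0.01
        mcf = mark_connection(table, *cfg.class_labels, n_permutations=99, seed=2)
        assert exclusivity_verdict(mcf, 200.0).summary == "repulsion"


class TestMarkConnection:
    BINS = np.array([0.0, 50.0, 100.0, 200.0])

    def test_single_class_has_zero_cross_probability(self, rng):
        table = make_table(rng.uniform(0, 300, (20, 2)), "A")
        mcf = mark_connection(table, "A", "B", self.BINS, n_permutations=0)
        nonempty = mcf.n_pairs > 0
        assert nonempty.any()
        assert np.all(mcf.p_cross[nonempty] == 0.0)

    def test_four_point_fixture_matches_exhaustive_pairs(self):
        pts = [[0, 0], [30, 0], [100, 0], [160, 0]]
        labels = ["A", "B", "A", "B"]
        table = make_table(pts, labels)
        mcf = mark_connection(table, "A", "B", self.BINS, n_permutations=0)
        expected, total = mcf_bruteforce(pts, labels, self.BINS)
        # distances: 30(AB) | 70(BA), 60(AB) | 100(AA), 160(AB), 130(BB)
        assert total.tolist() == [1, 2, 3]
        assert expected.tolist() == [1.0, 1.0, pytest.approx(1 / 3)]
        assert np.array_equal(mcf.p_cross, expected, equal_nan=True)
        assert np.array_equal(mcf.n_pairs, total)

    def test_random_point_sets_match_bruteforce_exactly(self, rng):
        for _ in range(3):
            n = int(rng.integers(50, 200))
            pts = rng.uniform(0, 600, size=(n, 2))
            labels = np.where(rng.random(n) < 0.4, "A", "B")
            table = make_table(pts, labels)
            bins = np.array([0.0, 40.0, 90.0, 150.0, 300.0])
            mcf = mark_connection(table, "A", "B", bins, n_permutations=0)
            expected, total = mcf_bruteforce(pts, labels, bins)
            assert np.array_equal(mcf.n_pairs, total)
            assert np.allclose(mcf.p_cross, expected, equal_nan=True)

    def test_random_allocation_normalises_to_one(self, rng):
        centres = rng.uniform(0, 3000, size=(15, 2))
        pts = np.vstack([c + rng.normal(0, 21, size=(40, 2)) for c in centres])
        means = []
        for _ in range(20):
            labels = np.where(rng.random(len(pts)) < 0.5, "A", "B")
            mcf = mark_connection(make_table(pts, labels), "A", "B", n_permutations=0)
            means.append(np.nanmean(mcf.normalised))
        assert np.mean(means) == pytest.approx(1.0, abs=0.05)

    def test_label_swap_symmetry(self, rng):
        pts = rng.uniform(0, 500, size=(80, 2))
        labels = np.where(rng.random(80) < 0.3, "A", "B")
        table = make_table(pts, labels)
        m1 = mark_connection(table, "A", "B", self.BINS, n_permutations=19, seed=5)
        m2 = mark_connection(table, "B", "A", self.BINS, n_permutations=19, seed=5)
        for attr in ("p_cross", "normalised", "centred", "envelope_low", "envelope_high"):
            assert np.array_equal(getattr(m1, attr), getattr(m2, attr), equal_nan=True)

    def test_null_envelope_calibration(self, rng):
        """Randomly allocated labels land inside the 95% envelope in ~95% of bins."""
        centres = rng.uniform(0, 2500, size=(12, 2))
        pts = np.vstack([c + rng.normal(0, 21, size=(30, 2)) for c in centres])
        inside = total = 0
        for seed in range(8):
            labels = np.where(rng.random(len(pts)) < 0.5, "A", "B")
            mcf = mark_connection(
                make_table(pts, labels), "A", "B", n_permutations=199, seed=seed
            )
            ok = mcf.n_pairs > 0
            inside += int(
                np.sum(
                    (mcf.centred[ok] >= mcf.envelope_low[ok])
                    & (mcf.centred[ok] <= mcf.envelope_high[ok])
                )
            )
            total += int(ok.sum())
        assert 0.85 <= inside / total <= 1.0

    def test_empty_bins_flagged_not_dropped(self, rng):
        table = make_table([[0, 0], [10, 0], [400, 0]], ["A", "B", "A"])
        bins = np.array([0.0, 50.0, 100.0, 500.0])
        mcf = mark_connection(table, "A", "B", bins, n_permutations=0)
        assert mcf.empty_bins.tolist() == [False, True, False]
        assert np.isnan(mcf.p_cross[1])

    def test_pair_counting_respects_roi_boundaries(self):
        pts = [[0, 0], [20, 0], [0, 0], [20, 0]]
        table = make_table(pts, ["A", "B", "B", "A"], ["r1", "r1", "r2", "r2"])
        mcf = mark_connection(table, "A", "B", np.array([0.0, 50.0]), n_permutations=0)
        assert mcf.n_pairs.tolist() == [2]  # within-ROI pairs only, not 4

    def test_periodic_box_wraps_distances(self):
        table = make_table([[5, 5], [995, 995]], ["A", "B"])
        no_box = mark_connection(table, "A", "B", np.array([0.0, 50.0]), n_permutations=0)
        boxed = mark_connection(
            table, "A", "B", np.array([0.0, 50.0]), n_permutations=0, box=1000.0
        )
        assert no_box.n_pairs.tolist() == [0]
        assert boxed.n_pairs.tolist() == [1]
        assert boxed.p_cross[0] == 1.0


class TestVerdict:
    def test_all_inside_envelope_is_random(self, rng):
        pts = rng.uniform(0, 1000, size=(150, 2))
        labels = np.where(rng.random(150) < 0.5, "A", "B")
        mcf = mark_connection(make_table(pts, labels), "A", "B", n_permutations=199, seed=3)
        v = exclusivity_verdict(mcf, 200.0)
        assert v.summary == "random"

    def test_exclusive_fibre_shows_repulsion_below_200nm(self):
        (table, _), cfg = exclusive_fibre(seed=12)
        mcf = mark_connection(table, *cfg.class_labels, n_permutations=99, seed=4)
        v = exclusivity_verdict(mcf, 200.0)
        assert v.summary == "repulsion"
        assert v.per_bin[0] == "repulsion"

    def test_paired_marks_show_attraction(self, rng):
        """Tight A-B doublets make nearly every short-distance pair a cross pair,
        pushing the centred MCF above the random-labelling envelope."""
        centres = rng.uniform(0, 6000, size=(120, 2))
        pts_a = centres + rng.normal(0, 8, size=centres.shape)
        pts_b = centres + rng.normal(0, 8, size=centres.shape)
        table = make_table(
            np.vstack([pts_a, pts_b]), ["A"] * len(pts_a) + ["B"] * len(pts_b)
        )
        mcf = mark_connection(table, "A", "B", n_permutations=99, seed=6)
        v = exclusivity_verdict(mcf, 40.0)  # doublet separations are < 40 nm
        assert v.summary == "attraction"

    def test_no_nonempty_bins_below_limit_errors(self):
        table = make_table([[0, 0], [400, 0]], ["A", "B"])
        mcf = mark_connection(table, "A", "B", np.array([0.0, 100.0, 500.0]), n_permutations=9)
        with pytest.raises(AnalysisError):
            exclusivity_verdict(mcf, 100.0)
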