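"""Experiment drivers: naming, layer profiles, triplets, shape vs category."""

import numpy as np
import pytest
from scipy.stats import ortho_group, spearmanr

import shapesim as ss
from shapesim import experiments as exp
from shapesim.models import FeatureMatrix


class TestScoreNaming:
    def make_dataset(self, model_resp):
        items = ["dog", "car"]
        return exp.NamingDataset(
            item_ids=items,
            true_labels={"dog": "dog", "car": "car"},
            synonyms={"dog": {"dog", "puppy"}, "car": {"car", "auto"}},
            human_responses={"p0": ["dog", "car"], "p1": ["puppy", "auto"]},
            model_responses={"m": model_resp},
        )

    def test_perfect_model_consistency_one(self):
        res = exp.score_naming(self.make_dataset(["dog", "car"]), n_iter=50)
        assert res.human_model_consistency["m"] == pytest.approx(1.0)
        assert res.model_accuracy["m"] == 1.0

    def test_synonyms_count_as_correct(self):
        res = exp.score_naming(self.make_dataset(["puppy", "auto"]), n_iter=50)
        assert res.model_accuracy["m"] == 1.0

    def test_response_outside_closed_list_rejected(self):
        with pytest.raises(ValueError, match="banana"):
            self.make_dataset(["banana", "car"])

    def test_half_agreement_gives_half_consistency(self):
        """Binary items where the model matches mean-human accuracy on half
        the items: consistency 1.0 when matched everywhere, 0.5 after
        flipping the model on half the items."""
        human = np.array([[1, 1, 0, 0]], dtype=float)
        matched = {"m": np.array([1, 1, 0, 0], dtype=float)}
        flipped = {"m": np.array([0, 0, 0, 0], dtype=float)}
        r1 = exp.score_correctness(human, matched, n_iter=50)
        r2 = exp.score_correctness(human, flipped, n_iter=50)
        assert r1.human_model_consistency["m"] == pytest.approx(1.0)
        assert r2.human_model_consistency["m"] == pytest.approx(0.5)

    def test_consistency_rises_with_panel_size(self):
        """A model sharing the humans' item difficulties agrees more with the
        panel mean as the panel grows (Monte-Carlo, 50 replicates)."""
        p = np.random.default_rng(3).uniform(0.2, 0.95, 40)
        cons = {n: [] for n in (2, 30)}
        for rep in range(50):
            model = ss.simulate_naming(p, 1, seed=10_000 + rep)[0]
            for n in cons:
                panel = ss.simulate_naming(p, n, seed=rep * 100 + n)
                cons[n].append(ss.consistency(model, panel.mean(axis=0)))
        assert np.mean(cons[30]) > np.mean(cons[2])


class TestSlopeTest:
    def test_null_calibration(self):
        """Model correctness independent of human accuracy: |z| < 1.96 in at
        least 90% of 200 simulations."""
        calm = 0
        for sim in range(200):
            rng = np.random.default_rng(sim)
            human = rng.uniform(0.1, 0.9, 60)
            model = (rng.random(60) < 0.5).astype(float)
            res = exp.naming_slope_test(human, model)
            if res.method == "wald" and abs(res.z) < 1.96:
                calm += 1
        assert calm >= 0.90 * 200

    def test_planted_association_positive_slope(self):
        rng = np.random.default_rng(7)
        human = rng.uniform(0, 1, 80)
        model = ((human + rng.normal(0, 0.2, 80)) > 0.5).astype(float)
        res = exp.naming_slope_test(human, model)
        assert res.z > 0 and res.slope > 0

    def test_constant_model_degenerate(self):
        res = exp.naming_slope_test(np.linspace(0, 1, 10), np.ones(10))
        assert res.method == "degenerate" and np.isnan(res.slope)

    def test_separation_uses_fallback_not_crash(self):
        human = np.linspace(0, 1, 40)
        model = (human > 0.5).astype(float)  # complete separation
        res = exp.naming_slope_test(human, model)
        assert res.method in ("wald", "lrt-ridge")
        assert np.isfinite(res.p) and res.p < 0.05 and res.slope > 0


class TestPhysicalVsPerceived:
    def test_pixelwise_prefers_physical(self, references):
        pix, rdm_physical, rdm_perceived = references
        profile = ss.physical_vs_perceived([pix], rdm_physical, rdm_perceived,
                                           n_iter=100, seed=0)
        assert (profile.correlations("physical")[0]
                > profile.correlations("perceived")[0])

    def test_perceived_embodying_layer_wins_with_ci(self, references):
        """A layer sampled to embody the perceived RDM exactly correlates ~1
        with it, with a CI excluding the physical correlation."""
        _, rdm_physical, rdm_perceived = references
        plan = ss.LayerMixPlan(mix_weights=(1.0,), noise_sd=0.0, seed=2)
        layer = ss.simulate_layer_features(plan, rdm_physical, rdm_perceived)
        profile = ss.physical_vs_perceived(layer, rdm_physical, rdm_perceived,
                                           n_iter=200, seed=0)
        perc = profile.references["perceived"][0]
        phys = profile.references["physical"][0]
        assert perc.point > 0.95
        assert perc.ci_low > phys.point

    def test_mismatched_references_raise(self, references, rng):
        from conftest import random_rdm

        pix, rdm_physical, _ = references
        with pytest.raises(ValueError, match="stimulus order"):
            ss.physical_vs_perceived([pix], rdm_physical, random_rdm(9, rng))

    def test_end_to_end_crossover_sign(self, references):
        """With the default monotone plan, perceived correlation rises from
        bottom to top layer while physical falls."""
        _, rdm_physical, rdm_perceived = references
        plan = ss.LayerMixPlan(noise_sd=0.1, seed=0)
        layers = ss.simulate_layer_features(plan, rdm_physical, rdm_perceived)
        profile = ss.physical_vs_perceived(layers, rdm_physical, rdm_perceived,
                                           n_iter=50, seed=0)
        perc, phys = profile.correlations("perceived"), profile.correlations("physical")
        assert perc[-1] - perc[0] > 0
        assert phys[-1] - phys[0] < 0


class TestNapEvaluate:
    def test_random_triplets_at_chance(self):
        rng = np.random.default_rng(0)
        n = 2000
        sets = ss.TripletSet(
            bases=rng.normal(size=(n, 50)),
            nap_variants=rng.normal(size=(n, 50)),
            metric_variants=rng.normal(size=(n, 50)),
            diagnostic_dim=5,
        )
        res = exp.nap_evaluate(sets, metric="correlation", n_iter=100, seed=0)
        assert res.accuracy == pytest.approx(0.5, abs=0.03)

    def test_planted_sets_hit_floor_and_ceiling(self):
        linear, perceptual = ss.generate_triplet_features(seed=1)
        assert exp.nap_evaluate(linear, n_iter=50, seed=0).accuracy == 0.0
        assert exp.nap_evaluate(perceptual, n_iter=50, seed=0).accuracy == 1.0

    def test_ties_counted_separately_not_crash(self):
        base = np.tile(np.arange(4.0), (3, 1))
        sets = ss.TripletSet(bases=base, nap_variants=base.copy(),
                             metric_variants=base.copy(), diagnostic_dim=1)
        res = exp.nap_evaluate(sets, metric="euclidean", n_iter=50, seed=0)
        assert res.accuracy == 0.0 and res.n_ties == 3

    def test_orthogonal_invariance_normalized_euclidean(self):
        """Accuracy is invariant under a common orthogonal transform of
        feature space for the normalized-Euclidean metric."""
        linear, perceptual = ss.generate_triplet_features(n_triplets=10, seed=5)
        q = ortho_group.rvs(100, random_state=3)
        rotated = ss.TripletSet(
            bases=perceptual.bases @ q,
            nap_variants=perceptual.nap_variants @ q,
            metric_variants=perceptual.metric_variants @ q,
            diagnostic_dim=perceptual.diagnostic_dim,
        )
        a = exp.nap_evaluate(perceptual, metric="normalized_euclidean",
                             n_iter=50, seed=0)
        b = exp.nap_evaluate(rotated, metric="normalized_euclidean",
                             n_iter=50, seed=0)
        np.testing.assert_array_equal(a.outcomes, b.outcomes)


class TestShapeVsCategory:
    def _design(self, n_cat=6, n_shape=9):
        ids = [f"c{c}_s{s}" for c in range(n_cat) for s in range(n_shape)]
        cat = [i.split("_")[0] for i in ids]
        shp = [i.split("_")[1] for i in ids]
        return ids, ss.class_block_rdm(shp, ids), ss.class_block_rdm(cat, ids)

    def test_balanced_references_near_orthogonal(self):
        """In the balanced 6x9 design the shape and category block RDMs share
        no positive structure (small negative overlap from exclusivity)."""
        _, rdm_shape, rdm_category = self._design()
        r = ss.rdm_correlation(rdm_shape, rdm_category)
        assert abs(r) < 0.15

    def test_category_only_layer_prefers_category(self):
        ids, rdm_shape, rdm_category = self._design(3, 4)
        plan = ss.LayerMixPlan(mix_weights=(1.0,), n_features=50, noise_sd=0.0,
                               seed=0)
        layer = ss.simulate_layer_features(plan, rdm_shape, rdm_category)
        profile = ss.shape_vs_category(layer, rdm_shape, rdm_category,
                                       n_iter=200, seed=0, stratified=True)
        cat = profile.references["category"][0]
        shp = profile.references["shape"][0]
        assert cat.point > shp.point
        assert cat.ci_low > shp.ci_high  # non-overlapping CIs

    def test_silhouette_pixels_prefer_shape(self):
        """Pixelwise features of silhouettes sharing a contour per shape
        group track the shape RDM, not the category RDM."""
        designs = []
        for c in range(3):
            for s in range(3):
                rng = np.random.default_rng(s)  # contour depends on shape only
                img = np.ones((64, 64))
                r0, c0 = 10 + 4 * s, 10 + 4 * s
                img[r0:r0 + 20, c0:c0 + 20] = 0.0
                designs.append(ss.ImageStimulus(
                    pixels=img, label=f"c{c}_s{s}",
                    class_labels={"category": f"c{c}", "shape": f"s{s}"}))
        fm = ss.stack_features(designs, ss.pixelwise_features, model_name="pix")
        ids = fm.stimulus_ids
        rdm_shape = ss.class_block_rdm([d.class_labels["shape"] for d in designs], ids)
        rdm_cat = ss.class_block_rdm([d.class_labels["category"] for d in designs], ids)
        profile = ss.shape_vs_category([fm], rdm_shape, rdm_cat,
                                       n_iter=100, seed=0, stratified=True)
        assert (profile.references["shape"][0].point
                > profile.references["category"][0].point)

    def test_missing_strata_raise(self):
        ids, rdm_shape, rdm_category = self._design(3, 4)
        bare = ss.RDM(values=rdm_shape.values, stimulus_ids=ids)
        with pytest.raises(ValueError, match="strata"):
            ss.shape_vs_category([], bare, rdm_category, stratified=True)


class TestCompareModelGroups:
    def test_better_group_detected(self, references):
        _, rdm_physical, rdm_perceived = references
        plan_hi = ss.LayerMixPlan(mix_weights=(1.0, 0.9), noise_sd=0.05, seed=1)
        plan_lo = ss.LayerMixPlan(mix_weights=(0.0, 0.1), noise_sd=0.05, seed=2)
        hi = [ss.compute_rdm(l) for l in
              ss.simulate_layer_features(plan_hi, rdm_physical, rdm_perceived)]
        lo = [ss.compute_rdm(l) for l in
              ss.simulate_layer_features(plan_lo, rdm_physical, rdm_perceived)]
        out = exp.compare_model_groups(hi, lo, rdm_perceived, tail="one",
                                       n_iter=500, seed=0)
        assert out["p"] <= 0.01
        assert out["group1_mean"] > out["group2_mean"]
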