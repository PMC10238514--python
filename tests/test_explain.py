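import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from catpain import (
    Dataset, ModelSpec, consistency_summary, gradcam, heat_at_landmarks,
    landmark_importance_mdi, make_subject_folds, occlusion_study,
)
from catpain.cnn import CnnStandin
from catpain.errors import BoundsError, CapabilityError, TaggingError, ValidationError
from catpain.explain import OcclusionStudy
from catpain.features import FeatureTag, coordinate_tags
from catpain.landmarks import LandmarkSet
from catpain.regions import RegionMap


# ---------------------------------------------------------------- occlusion

def _planted_dataset(template, rng, n=16):
    mouth = list(template.region_map.indices("mouth"))
    sets, labels = [], []
    for i in range(n):
        y = i % 2
        coords = template.coords + rng.normal(0, 1.0, (48, 2))
        if y:
            coords[mouth] += 6.0
        sets.append(LandmarkSet(f"img{i}", f"s{i}", coords))
        labels.append(y)
    return Dataset(labels=np.array(labels),
                   subject_ids=np.array([s.subject_id for s in sets]),
                   sets=sets, template=template)


class TestOcclusionStudy:
    def test_row_count_and_schema(self, template, rng):
        data = _planted_dataset(template, rng)
        plan = make_subject_folds(data.subject_ids, 4, seed=0)
        study = occlusion_study(data, ModelSpec("random_forest", max_depth=4, n_trees=30),
                                plan)
        assert list(study.table.columns) == ["Region", "Config", "Accuracy",
                                             "Precision", "Recall"]
        assert len(study.table) == 7  # 1 + 2 regions * 3
        assert study.table["Config"].tolist() == [
            "Full", "Reveal only", "Hide", "Reveal only", "Hide", "Reveal only", "Hide"]

    def test_planted_region_tops_reveal_only(self, template, rng):
        data = _planted_dataset(template, rng, n=24)
        plan = make_subject_folds(data.subject_ids, 4, seed=1)
        study = occlusion_study(data, ModelSpec("random_forest", max_depth=5, n_trees=60),
                                plan)
        summary = study.ranked_summary()
        assert summary["reveal_highest"] == "Mouth"

    def test_zero_feature_config_is_a_failed_row(self, template, rng):
        from catpain.features import VectorScheme, featurize_sets

        data = _planted_dataset(template, rng, n=8)
        scheme = VectorScheme(pairs={"mouth": ((24, 25), (25, 26))},
                              region_map=template.region_map)
        data.featurizer = lambda sets: featurize_sets(sets, scheme)
        plan = make_subject_folds(data.subject_ids, 2, seed=0)
        study = occlusion_study(data, ModelSpec("random_forest", max_depth=3, n_trees=10),
                                plan)
        assert "Ears:Reveal only" in study.failed
        assert len(study.table) == 7
        assert study.table.loc[study.table["Region"] == "Ears", "Accuracy"].isna().any()


# --------------------------------------------------------------- importance

class TestLandmarkImportance:
    def test_only_split_landmark_gets_weight(self, rng):
        # features: x/y of two landmarks; only landmark 0's x is informative
        region_map = RegionMap({"ears": (0,), "eyes": (1,), "mouth": ()})
        X = rng.normal(0, 1, size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        forest = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
        tags = [FeatureTag("x0", "ears", (0,)), FeatureTag("y0", "ears", (0,)),
                FeatureTag("x1", "eyes", (1,)), FeatureTag("y1", "eyes", (1,))]
        imap = landmark_importance_mdi(forest, tags, region_map)
        assert imap.normalized[0] == 1.0
        assert imap.normalized[1] < 0.05
        assert imap.highlight.tolist() == [True, False]

    def test_matches_hand_walked_two_tree_ensemble(self, rng):
        """MDI recomputed from raw tree arrays: weighted impurity decreases,
        normalized per tree, averaged over trees, summed per landmark."""
        X = rng.normal(0, 1, size=(40, 4))
        y = ((X[:, 0] + 0.5 * X[:, 2]) > 0).astype(int)
        forest = RandomForestClassifier(n_estimators=2, bootstrap=False,
                                        random_state=1).fit(X, y)

        def tree_mdi(tree):
            t = tree.tree_
            imp = np.zeros(X.shape[1])
            for node in range(t.node_count):
                left, right = t.children_left[node], t.children_right[node]
                if left == -1:
                    continue
                n, nl, nr = (t.weighted_n_node_samples[i] for i in (node, left, right))
                decrease = n * t.impurity[node] - nl * t.impurity[left] - nr * t.impurity[right]
                imp[t.feature[node]] += decrease
            imp /= t.weighted_n_node_samples[0]
            return imp / imp.sum()

        oracle_features = np.mean([tree_mdi(e) for e in forest.estimators_], axis=0)
        tags = [FeatureTag(f"f{i}", "ears", (i % 2,)) for i in range(4)]
        region_map = RegionMap({"ears": (0, 1), "eyes": (), "mouth": ()})
        imap = landmark_importance_mdi(forest, tags, region_map)
        oracle_landmarks = np.zeros(2)
        for i, v in enumerate(oracle_features):
            oracle_landmarks[i % 2] += v
        np.testing.assert_allclose(imap.raw, oracle_landmarks, atol=1e-12)
        assert oracle_features.sum() == pytest.approx(1.0)

    def test_column_order_invariance_given_tags(self, template, rng):
        class _Fitted:  # minimal ensemble stand-in exposing MDI importances
            def __init__(self, imp):
                self.feature_importances_ = imp

        imp = rng.dirichlet(np.ones(96))
        tags = coordinate_tags(template.region_map)
        base = landmark_importance_mdi(_Fitted(imp), tags, template.region_map)
        perm = rng.permutation(96)
        permuted = landmark_importance_mdi(_Fitted(imp[perm]), [tags[i] for i in perm],
                                           template.region_map)
        np.testing.assert_allclose(base.raw, permuted.raw, atol=1e-12)
        np.testing.assert_allclose(base.normalized, permuted.normalized, atol=1e-12)

    def test_untagged_feature_errors(self, rng):
        X = rng.normal(0, 1, (30, 2))
        y = (X[:, 0] > 0).astype(int)
        forest = RandomForestClassifier(n_estimators=5, random_state=0).fit(X, y)
        tags = [FeatureTag("a", "ears", ()), FeatureTag("b", "ears", (0,))]
        with pytest.raises(TaggingError):
            landmark_importance_mdi(forest, tags, RegionMap({"ears": (0,), "eyes": (), "mouth": ()}))


# ----------------------------------------------------------------- gradcam

class TestGradCam:
    def test_one_by_one_conv_closed_form(self):
        model = CnnStandin(input_size=4, n_filters=2, filter_size=1, stride=1)
        model._mean, model._std = 0.0, 1.0
        model.init_parameters()
        model.W1 = np.array([[1.0], [-1.0]])
        model.b1 = np.array([0.0, 0.5])
        model.W2 = np.array([[2.0, 1.0], [0.0, 0.0]])
        model.b2 = np.zeros(2)
        img = np.array([[0.1, -0.2, 0.0, 0.3]] * 4)
        cam = model.gradcam(img, target_class=0)
        a0 = np.maximum(img, 0.0)            # filter 1: identity
        a1 = np.maximum(-img + 0.5, 0.0)     # filter 2: negate + bias
        expected = np.maximum(2.0 * a0 + 1.0 * a1, 0.0)
        expected /= expected.max()
        np.testing.assert_allclose(cam, expected, atol=1e-7)

    def test_zero_weight_head_gives_zero_map(self):
        model = CnnStandin(input_size=8, n_filters=3, filter_size=3, stride=1)
        model._mean, model._std = 0.0, 1.0
        model.init_parameters()
        model.W2 = np.zeros_like(model.W2)
        cam = model.gradcam(np.random.default_rng(0).random((8, 8)), target_class=1)
        np.testing.assert_array_equal(cam, 0.0)

    def test_non_convolutional_model_rejected(self, rng):
        forest = RandomForestClassifier(n_estimators=2, random_state=0)
        forest.fit(rng.normal(size=(10, 3)), [0, 1] * 5)
        with pytest.raises(CapabilityError):
            gradcam(forest, np.zeros((8, 8)), 0)

    def test_cnn_learns_planted_renders(self, template, rng):
        from catpain.synthetic import render_face

        mouth = list(template.region_map.indices("mouth"))
        images, labels = [], []
        for i in range(30):
            y = i % 2
            coords = template.coords.copy()
            if y:
                coords[mouth] += 10.0
            coords += rng.normal(0, 1.0, (48, 2))
            images.append(render_face(coords, (256, 256), template.region_map) / 255.0)
            labels.append(y)
        model = CnnStandin(epochs=150, seed=0).fit(np.stack(images), np.array(labels))
        assert (model.predict(np.stack(images)) == labels).mean() >= 0.9


# -------------------------------------------------------------------- heat

class TestHeatAtLandmarks:
    def _sets(self, template, n=3):
        return [LandmarkSet(f"img{i}", f"s{i}", template.coords) for i in range(n)]

    def test_uniform_heat_normalizes_to_255_everywhere(self, template):
        sets = self._sets(template)
        maps = [np.full((256, 256), 0.37) for _ in sets]
        profile = heat_at_landmarks(maps, sets, template.region_map)
        np.testing.assert_allclose(profile.scaled, 255.0)
        assert profile.region_ratios() == {"ears": 1.0, "eyes": 1.0, "mouth": 1.0}

    def test_delta_field_hits_single_landmark(self, template):
        sets = self._sets(template, n=1)
        hm = np.zeros((256, 256))
        x, y = template.coords[5]
        hm[int(round(y)), int(round(x))] = 1.0
        profile = heat_at_landmarks([hm], sets, template.region_map)
        assert profile.scaled[5] == 255.0
        others = np.delete(profile.scaled, 5)
        np.testing.assert_array_equal(others, 0.0)

    def test_matches_naive_double_loop_oracle(self, template, rng):
        sets = [LandmarkSet(f"i{k}", f"s{k}", template.coords + rng.normal(0, 2, (48, 2)))
                for k in range(4)]
        maps = [rng.random((256, 256)) for _ in sets]
        profile = heat_at_landmarks(maps, sets, template.region_map)
        oracle = np.zeros(48)
        for hm, s in zip(maps, sets):  # naive double loop
            for lm in range(48):
                col = min(max(int(round(s.coords[lm, 0])), 0), 255)
                row = min(max(int(round(s.coords[lm, 1])), 0), 255)
                oracle[lm] += hm[row, col]
        oracle /= len(maps)
        np.testing.assert_array_equal(profile.raw, oracle)
        np.testing.assert_allclose(profile.scaled, oracle * 255.0 / oracle.max(), atol=1e-12)

    def test_positive_scaling_invariance(self, template, rng):
        sets = self._sets(template, n=2)
        maps = [rng.random((256, 256)) for _ in sets]
        a = heat_at_landmarks(maps, sets, template.region_map)
        b = heat_at_landmarks([3.7 * m for m in maps], sets, template.region_map)
        np.testing.assert_allclose(a.scaled, b.scaled, atol=1e-9)

    def test_rgb_maps_use_red_channel(self, template, rng):
        sets = self._sets(template, n=1)
        red = rng.random((256, 256))
        rgb = np.stack([red, rng.random((256, 256)), rng.random((256, 256))], axis=-1)
        np.testing.assert_array_equal(
            heat_at_landmarks([rgb], sets, template.region_map).raw,
            heat_at_landmarks([red], sets, template.region_map).raw)

    def test_out_of_raster_landmark_errors(self, template):
        coords = template.coords.copy()
        coords[7] = (300.0, 10.0)
        s = LandmarkSet("img-bad", "s", coords)
        with pytest.raises(BoundsError, match="img-bad"):
            heat_at_landmarks([np.zeros((256, 256))], [s], template.region_map)


# ------------------------------------------------------------- consistency

class TestConsistencySummary:
    def _study(self, accs: dict[str, float], full=0.8) -> OcclusionStudy:
        rows = [{"Region": "All", "Config": "Full", "Accuracy": full,
                 "Precision": full, "Recall": full}]
        for region, acc in accs.items():
            rows.append({"Region": region, "Config": "Reveal only", "Accuracy": acc,
                         "Precision": acc, "Recall": acc})
            rows.append({"Region": region, "Config": "Hide", "Accuracy": full - acc / 4,
                         "Precision": acc, "Recall": acc})
        return OcclusionStudy(pd.DataFrame(rows), {})

    def test_reported_pattern_agrees(self, template):
        # reveal-only: mouth best, ears worst; importance and heat concur
        study = self._study({"Ears": 0.41, "Eyes": 0.70, "Mouth": 0.72})
        raw = np.zeros(48)
        raw[list(template.region_map.indices("mouth"))] = 0.03
        raw[list(template.region_map.indices("eyes"))] = 0.01
        raw[list(template.region_map.indices("ears"))] = 0.005
        from catpain.explain import HeatProfile, ImportanceMap

        imap = ImportanceMap(raw, raw / raw.max(), raw / raw.max() >= 0.5,
                             template.region_map)
        scaled = raw * 255 / raw.max()
        heat = HeatProfile(raw, scaled, template.region_map)
        summary = consistency_summary({"LDM RF": study}, {"LDM RF": imap}, {"DL": heat})
        assert summary.agreement
        assert summary.consensus_highest == "Mouth"
        assert summary.consensus_lowest == "Ears"
        assert list(summary.table.columns) == ["Approach", "Instrument", "Highest", "Lowest"]

    def test_single_instrument_single_row_block(self):
        study = self._study({"Ears": 0.4, "Eyes": 0.6, "Mouth": 0.7})
        summary = consistency_summary({"only": study})
        assert len(summary.table) == 2  # reveal-only + hide rows
        assert summary.table["Instrument"].tolist() == ["Reveal only", "Hide"]

    def test_disagreement_unsets_consensus(self, template):
        from catpain.explain import ImportanceMap

        study = self._study({"Ears": 0.41, "Eyes": 0.70, "Mouth": 0.72})
        raw = np.zeros(48)
        raw[list(template.region_map.indices("ears"))] = 0.05  # contradicts occlusion
        imap = ImportanceMap(raw, raw / raw.max(), raw / raw.max() >= 0.5,
                             template.region_map)
        summary = consistency_summary({"LDM RF": study}, {"LDM RF": imap})
        assert not summary.agreement and summary.consensus_highest is None

    def test_no_inputs_errors(self):
        with pytest.raises(ValidationError):
            consistency_summary()


def test_synthetic_hot_region_ranks_highest_end_to_end(template):
    """Heatmaps planted on one region must rank that region highest after
    landmark-level aggregation — the generator/aggregator round trip."""
    from catpain import simulate_heatmap

    sets = [LandmarkSet(f"i{k}", f"s{k}", template.coords) for k in range(3)]
    maps = [simulate_heatmap(s, "nose-mouth", (256, 256), sigma=8.0,
                             region_map=template.region_map) for s in sets]
    profile = heat_at_landmarks(maps, sets, template.region_map)
    means = profile.region_means()
    assert max(means, key=means.get) == "mouth"
    summary = consistency_summary(heat_profiles={"synthetic": profile})
    assert summary.table.iloc[0]["Highest"] == "Mouth"


def test_cnn_sees_signal_through_reveal_only_mouth_mask(template, rng):
    """Band-masking everything but the mouth keeps a planted mouth signal
    learnable by the image branch."""
    from catpain import OcclusionConfig, compute_region_bands, mask_image
    from catpain.synthetic import render_face

    mouth = list(template.region_map.indices("mouth"))
    center = template.coords[mouth].mean(axis=0)
    sets, images, labels = [], [], []
    for i in range(30):
        y = i % 2
        coords = template.coords.copy()
        if y:  # muzzle expansion, the generator's kind of shape change
            coords[mouth] = center + 1.3 * (coords[mouth] - center)
        coords += rng.normal(0, 1.0, (48, 2))
        sets.append(LandmarkSet(f"i{i}", f"s{i}", coords))
        images.append(render_face(coords, (256, 256), template.region_map) / 255.0)
        labels.append(y)
    bands = compute_region_bands(sets, 256, template)
    masked = np.stack([mask_image(im, bands, OcclusionConfig.reveal_only("mouth"))
                       for im in images])
    model = CnnStandin(epochs=150, seed=0).fit(masked, np.array(labels))
    assert (model.predict(masked) == labels).mean() >= 0.8
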