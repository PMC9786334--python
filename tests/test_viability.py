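"""Classification rules, viability arithmetic, and replicate statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from gelmaquant import (
    LabelMap,
    NucleusRecord,
    ViabilityResult,
    aggregate_condition,
    classify_nuclei,
    compute_viability,
    count_image,
    generate_micrograph,
    jarque_bera,
    one_way_anova,
    SceneSpec,
)


def _one_nucleus(green_on: bool, red_on: bool):
    lab = np.zeros((10, 10), int)
    lab[3:7, 3:7] = 1
    g = np.full((10, 10), green_on)
    r = np.full((10, 10), red_on)
    return LabelMap(lab), g, r


class TestClassifyNuclei:
    def test_green_only_is_viable(self):
        (rec,) = classify_nuclei(*_one_nucleus(True, False))
        assert rec.klass == "viable"
        assert rec.overlap_green == 1.0 and rec.overlap_red == 0.0

    def test_red_takes_precedence_on_double_positive(self):
        (rec,) = classify_nuclei(*_one_nucleus(True, True))
        assert rec.klass == "dead"

    def test_neither_mask_is_unclassified(self):
        (rec,) = classify_nuclei(*_one_nucleus(False, False))
        assert rec.klass == "unclassified"

    def test_partial_overlap_respects_threshold(self):
        lab = np.zeros((10, 10), int)
        lab[0:10, 0:10] = 1
        g = np.zeros((10, 10), bool)
        g[:, :4] = True  # 40% overlap
        recs = classify_nuclei(LabelMap(lab), g, np.zeros((10, 10), bool), overlap_threshold=0.5)
        assert recs[0].klass == "unclassified"
        recs = classify_nuclei(LabelMap(lab), g, np.zeros((10, 10), bool), overlap_threshold=0.3)
        assert recs[0].klass == "viable"

    def test_centroid_mode(self):
        lab = np.zeros((10, 10), int)
        lab[3:7, 3:7] = 1
        g = np.zeros((10, 10), bool)
        g[4:6, 4:6] = True  # covers centroid only
        (rec,) = classify_nuclei(
            LabelMap(lab), g, np.zeros((10, 10), bool), mode="centroid"
        )
        assert rec.klass == "viable"

    def test_shape_mismatch_is_an_error(self):
        lab, g, r = _one_nucleus(True, False)
        with pytest.raises(ValueError, match="shape"):
            classify_nuclei(lab, g[:5], r)

    def test_matches_ground_truth_on_seeded_scene(self):
        spec = SceneSpec(image_shape=(640, 640), n_cells=300, true_viability=0.7, rng_seed=21)
        stack, truths = generate_micrograph(spec)
        res = count_image(stack)
        cent = np.array([r.centroid for r in res.records])
        klass = np.array([r.klass for r in res.records])
        hits = 0
        for t in truths:
            d = np.sqrt(((cent - t.centroid) ** 2).sum(1))
            j = d.argmin()
            if d[j] <= t.nucleus_radius:
                hits += klass[j] == ("viable" if t.is_viable else "dead")
        assert hits / len(truths) >= 0.98

    def test_count_conservation(self, small_scene):
        _, stack, _ = small_scene
        res = count_image(stack)
        assert res.result.n_total == res.labels.n_nuclei


class TestComputeViability:
    @pytest.mark.parametrize(
        "nv,nd,expected", [(19, 1, 95.0), (0, 5, 0.0), (5, 0, 100.0), (1, 3, 25.0)]
    )
    def test_ratio_arithmetic(self, nv, nd, expected):
        recs = [
            NucleusRecord(i + 1, (0.0, 0.0), 10, 1.0, 0.0, "viable") for i in range(nv)
        ] + [
            NucleusRecord(nv + i + 1, (0.0, 0.0), 10, 0.0, 1.0, "dead") for i in range(nd)
        ]
        res = compute_viability(recs)
        assert res.viability_percent == pytest.approx(expected)
        assert 0.0 <= res.viability_percent <= 100.0

    def test_all_unclassified_is_missing_not_zero(self):
        recs = [NucleusRecord(i + 1, (0.0, 0.0), 10, 0.0, 0.0, "unclassified") for i in range(3)]
        res = compute_viability(recs)
        assert not res.defined
        assert res.viability_percent is None
        assert res.n_unclassified == 3

    def test_unclassified_excluded_from_denominator(self):
        recs = [
            NucleusRecord(1, (0.0, 0.0), 10, 1.0, 0.0, "viable"),
            NucleusRecord(2, (0.0, 0.0), 10, 0.0, 1.0, "dead"),
            NucleusRecord(3, (0.0, 0.0), 10, 0.0, 0.0, "unclassified"),
        ]
        assert compute_viability(recs).viability_percent == pytest.approx(50.0)


class TestJarqueBera:
    def test_agrees_with_brute_force_moments(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = jarque_bera(x)
        d = x - x.mean()
        s = (d**3).mean() / (d**2).mean() ** 1.5
        k = (d**4).mean() / (d**2).mean() ** 2
        expected = len(x) / 6 * (s**2 + (k - 3) ** 2 / 4)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        # and with the reference implementation
        ref = sps.jarque_bera(x)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_skewed_sample_rejected(self):
        x = np.random.default_rng(0).exponential(size=200)
        assert not jarque_bera(x).normal

    def test_normal_sample_accepted(self):
        x = np.random.default_rng(1).normal(size=200)
        assert jarque_bera(x).normal

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            jarque_bera([2.0, 2.0, 2.0, 2.0])

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="n="):
            jarque_bera([1.0, 2.0, 4.0])


class TestAnova:
    def test_known_decomposition(self):
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.f == pytest.approx(3.0, rel=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_groups_not_significant(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.f == 0.0
        assert not res.significant

    def test_degenerate_within_variance(self):
        with pytest.warns(UserWarning, match="infinite"):
            res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert np.isinf(res.f) and res.p_value == 0.0 and res.significant

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(12345)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = [rng.normal(size=5) for _ in range(3)]
            rejections += one_way_anova(groups).significant
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_needs_two_groups_of_two(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2, 3]])
        with pytest.raises(ValueError):
            one_way_anova([[1, 2], [3]])


class TestAggregateCondition:
    def test_single_condition_constant_replicates(self):
        per_image = [
            ("s1", ViabilityResult(95, 5)),
            ("s2", ViabilityResult(190, 10)),
            ("s3", ViabilityResult(380, 20)),
        ]
        gs = aggregate_condition(per_image, {"s1": "A", "s2": "A", "s3": "A"})
        assert gs.means["A"] == pytest.approx(95.0)
        assert gs.sds["A"] == pytest.approx(0.0)
        assert gs.anova is None  # single condition

    def test_identical_conditions_not_significant(self):
        per_image = []
        grouping = {}
        for cond in ("A", "B"):
            for i, (nv, nd) in enumerate([(90, 10), (92, 8), (88, 12)]):
                sid = f"{cond}{i}"
                per_image.append((sid, ViabilityResult(nv, nd)))
                grouping[sid] = cond
        gs = aggregate_condition(per_image, grouping)
        assert gs.anova.f == pytest.approx(0.0)
        assert not gs.anova.significant

    def test_pooling_weights_frames_by_cell_count(self):
        per_image = [("s1", ViabilityResult(99, 1)), ("s1", ViabilityResult(0, 1))]
        pooled = aggregate_condition(per_image, {"s1": "A", "s2": "A"}, pooling="pooled")
        framed = aggregate_condition(per_image, {"s1": "A", "s2": "A"}, pooling="frame")
        assert pooled.means["A"] == pytest.approx(100 * 99 / 101)
        assert framed.means["A"] == pytest.approx((99.0 + 0.0) / 2)

    def test_single_replicate_condition_excluded_with_warning(self):
        per_image = [
            ("a1", ViabilityResult(9, 1)),
            ("a2", ViabilityResult(8, 2)),
            ("b1", ViabilityResult(7, 3)),
        ]
        grouping = {"a1": "A", "a2": "A", "b1": "B"}
        with pytest.warns(UserWarning, match="single replicate"):
            gs = aggregate_condition(per_image, grouping)
        assert gs.anova is None
        assert gs.means["B"] == pytest.approx(70.0)

    def test_unmapped_sample_is_an_error(self):
        with pytest.raises(ValueError, match="condition"):
            aggregate_condition([("x", ViabilityResult(1, 1))], {})
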