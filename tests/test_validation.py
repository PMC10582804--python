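import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spinebn.inference import Evidence
from spinebn.io import load_containment_reference, load_judgment_agreement
from spinebn.validation import (
    AgreementError,
    AgreementTable,
    CaseRecord,
    LabelError,
    apply_variation,
    band_summary,
    containment_check,
    framework_summary,
    gwet_ac2,
    identity_weights,
    landis_koch,
    linear_weights,
    predictive_validation,
    roc_auc,
)


def table_from_pairs(pairs):
    return AgreementTable(
        ratings=pd.DataFrame(pairs, columns=["r1", "r2"]), categories=("A", "B")
    )


class TestGwetAC2:
    def test_perfect_agreement(self):
        result = gwet_ac2(table_from_pairs([["A", "A"], ["B", "B"], ["A", "A"]]))
        assert result.coefficient == pytest.approx(1.0)

    def test_hand_computed_example(self):
        result = gwet_ac2(
            table_from_pairs([["A", "A"], ["A", "A"], ["A", "B"], ["B", "B"]])
        )
        assert result.p_a == pytest.approx(0.75)
        assert result.p_e == pytest.approx(0.46875)
        assert result.coefficient == pytest.approx(0.5294, abs=5e-5)

    def test_always_disagree(self):
        result = gwet_ac2(
            table_from_pairs([["A", "B"], ["B", "A"], ["A", "B"], ["B", "A"]])
        )
        assert result.coefficient == pytest.approx(-1.0)

    def test_single_category_marginals_still_defined(self):
        result = gwet_ac2(table_from_pairs([["A", "A"], ["A", "A"]]))
        assert result.p_e < 1.0
        assert result.coefficient == pytest.approx(1.0)

    def test_all_single_rater_undefined(self):
        table = AgreementTable(
            ratings=pd.DataFrame({"r1": ["A", "B"], "r2": [np.nan, np.nan]}),
            categories=("A", "B"),
        )
        with pytest.raises(AgreementError, match="single rater"):
            gwet_ac2(table)

    def test_category_mismatch_rejected(self):
        with pytest.raises(AgreementError, match="categories"):
            gwet_ac2(table_from_pairs([["A", "B"]]), identity_weights(("X", "Y")))

    def test_identity_weights_equal_independent_ac1(self):
        """AC2 with identity weights equals AC1 computed from first principles."""
        rng = np.random.default_rng(3)
        data = rng.choice(["A", "B", "C"], size=(30, 4))
        table = AgreementTable(ratings=pd.DataFrame(data), categories=("A", "B", "C"))
        result = gwet_ac2(table)

        # independent AC1: per-item agreement = fraction of agreeing pairs
        q = 3
        p_a_items = []
        pi = np.zeros(q)
        for row in data:
            counts = np.array([(row == c).sum() for c in ("A", "B", "C")])
            r = counts.sum()
            p_a_items.append((counts * (counts - 1)).sum() / (r * (r - 1)))
            pi += counts / r
        p_a = np.mean(p_a_items)
        pi /= len(data)
        p_e = (pi * (1 - pi)).sum() / (q - 1)
        assert result.coefficient == pytest.approx((p_a - p_e) / (1 - p_e), abs=1e-12)

    def test_relabeling_invariance_under_identity_weights(self):
        rng = np.random.default_rng(9)
        data = rng.choice(["A", "B"], size=(20, 3))
        swapped = np.where(data == "A", "B", "A")
        r1 = gwet_ac2(AgreementTable(pd.DataFrame(data), categories=("A", "B")))
        r2 = gwet_ac2(AgreementTable(pd.DataFrame(swapped), categories=("A", "B")))
        assert r1.coefficient == pytest.approx(r2.coefficient, abs=1e-12)

    def test_linear_weights_credit_near_misses(self):
        cats = ("low", "mid", "high")
        data = [["low", "mid"], ["mid", "high"], ["low", "low"], ["high", "high"]]
        table = AgreementTable(pd.DataFrame(data), categories=cats)
        weighted = gwet_ac2(table, linear_weights(cats))
        unweighted = gwet_ac2(table, identity_weights(cats))
        assert weighted.p_a > unweighted.p_a


class TestLandisKoch:
    @pytest.mark.parametrize(
        "value, band",
        [
            (-0.1, "Poor"),
            (0.0, "Slight"),
            (0.2, "Slight"),
            (0.34, "Fair"),
            (0.5, "Moderate"),
            (0.68, "Substantial"),
            (0.85, "Almost perfect"),
            (1.0, "Almost perfect"),
        ],
    )
    def test_bands(self, value, band):
        assert landis_koch(value) == band

    def test_above_one_rejected(self):
        with pytest.raises(AgreementError):
            landis_koch(1.01)

    @given(a=st.floats(-1, 1), b=st.floats(-1, 1))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_total_and_monotone(self, a, b):
        order = ["Poor", "Slight", "Fair", "Moderate", "Substantial", "Almost perfect"]
        lo, hi = min(a, b), max(a, b)
        assert order.index(landis_koch(lo)) <= order.index(landis_koch(hi))


class TestBandSummary:
    def test_published_judgment_coefficients(self):
        summary = band_summary(load_judgment_agreement())
        assert summary["counts"]["Almost perfect"] == 9
        assert summary["counts"]["Substantial"] == 1
        assert summary["counts"]["Fair"] == 1
        assert summary["labels"]["fracture"] == "Fair"
        assert summary["labels"]["irritability_of_pain"] == "Substantial"

    def test_empty_map(self):
        summary = band_summary({})
        assert all(v == 0 for v in summary["counts"].values())

    def test_single_moderate(self):
        assert band_summary({"x": 0.5})["counts"]["Moderate"] == 1


class TestContainment:
    def test_nerve_root_one_of_seven(self, default_net):
        report = containment_check(default_net, load_containment_reference())
        assert report.per_condition()["nerve_root_condition"] == (1, 7)

    def test_ces_factors(self, default_net):
        report = containment_check(default_net, load_containment_reference())
        contained = {
            r.node
            for r in report.rows
            if r.condition == "cauda_equina_syndrome" and r.contained
        }
        assert contained == {
            "bilateral_radicular_pain",
            "myotomal_weakness",
            "bladder_function_change",
            "bowel_function_change",
            "saddle_sensory_disturbance",
        }

    def test_unlinked_node_not_contained(self, default_net):
        """Night pain exists in the network but is not linked to the
        space-occupying lesion node, so it must not count as contained."""
        report = containment_check(default_net, load_containment_reference())
        row = next(
            r
            for r in report.rows
            if r.condition == "space_occupying_lesion" and r.factor == "Night pain"
        )
        assert not row.contained

    def test_empty_reference(self, default_net):
        assert containment_check(default_net, {}).rows == []

    def test_unknown_condition_rejected(self, default_net):
        with pytest.raises(LabelError):
            containment_check(default_net, {"stress_fracture": []})


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ((0.9, 0.8), (1, 0), 1.0),
            ((0.5, 0.5, 0.5, 0.5), (1, 0, 1, 0), 0.5),
            ((0.9, 0.8, 0.7, 0.6), (1, 0, 1, 0), 0.75),
        ],
    )
    def test_known_aucs(self, scores, labels, expected):
        assert roc_auc(scores, labels).auc == pytest.approx(expected)

    def test_single_class_undefined_not_raised(self):
        result = roc_auc((0.4, 0.6), (1, 1))
        assert result.auc is None
        assert "single-class" in result.diagnostic

    def test_pair_counting_matches_brute_force(self):
        rng = np.random.default_rng(17)
        scores = rng.random(40).round(1)  # coarse grid forces ties
        labels = rng.integers(0, 2, size=40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        wins = 0.0
        for sp in scores[labels == 1]:
            for sn in scores[labels == 0]:
                wins += 1.0 if sp > sn else 0.5 if sp == sn else 0.0
        expected = wins / (labels.sum() * (len(labels) - labels.sum()))
        assert roc_auc(scores, labels).auc == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(15))
    def test_pair_counting_matches_trapezoidal_curve(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(60).round(1)
        labels = rng.integers(0, 2, size=60)
        if labels.sum() in (0, 60):
            labels[0] = 1 - labels[0]
        result = roc_auc(scores, labels)
        assert result.fpr[0] == 0.0 and result.fpr[-1] == 1.0
        assert result.tpr[0] == 0.0 and result.tpr[-1] == 1.0
        assert np.all(np.diff(result.fpr) >= 0)
        assert np.all(np.diff(result.tpr) >= 0)
        assert result.auc == pytest.approx(np.trapezoid(result.tpr, result.fpr), abs=1e-12)


class TestCaseRecord:
    def test_label_outside_six_conditions_rejected(self):
        with pytest.raises(LabelError, match="stress"):
            CaseRecord(id="c1", evidence=Evidence({}), labels={"stress": 1})

    def test_non_binary_label_rejected(self):
        with pytest.raises(LabelError):
            CaseRecord(id="c1", evidence=Evidence({}), labels={"fracture": 2})


class TestApplyVariation:
    def ces_case(self, **labels):
        return CaseRecord(
            id="ces1",
            evidence=Evidence(
                {
                    "bilateral_radicular_pain": "present",
                    "myotomal_weakness": "present",
                    "bladder_function_change": "absent",
                }
            ),
            labels={"cauda_equina_syndrome": 1, **labels},
        )

    def test_higher_risk_sets_first_unset_sign(self, default_net):
        varied = apply_variation(self.ces_case(), "higher_risk", default_net)
        # first CES-linked sign in canonical order that is not already present
        assert varied.evidence.observations["bladder_function_change"] == "present"
        assert varied.labels == self.ces_case().labels

    def test_add_cancer_symptoms_sets_all_linked_signs(self, default_net):
        varied = apply_variation(self.ces_case(), "add_cancer_symptoms", default_net)
        for sign in default_net.children("space_occupying_lesion"):
            assert varied.evidence.observations[sign] == "present"

    def test_exhausted_variation_raises(self, default_net):
        full = CaseRecord(
            id="ces2",
            evidence=Evidence(
                {s: "present" for s in default_net.children("cauda_equina_syndrome")}
            ),
            labels={"cauda_equina_syndrome": 1},
        )
        with pytest.raises(ValueError, match="exhausted"):
            apply_variation(full, "higher_risk", default_net)


class TestPredictiveValidation:
    def test_separable_construction_gives_auc_one(self, default_model):
        net = default_model.net
        ces_signs = net.children("cauda_equina_syndrome")
        positive = CaseRecord(
            id="pos",
            evidence=Evidence({s: "present" for s in ces_signs}),
            labels={"cauda_equina_syndrome": 1},
        )
        negative = CaseRecord(
            id="neg",
            evidence=Evidence({s: "absent" for s in ces_signs}),
            labels={"cauda_equina_syndrome": 0},
        )
        results = predictive_validation(default_model, [positive, negative])
        assert results["cauda_equina_syndrome"].auc == pytest.approx(1.0)

    def test_degenerate_class_reported_undefined(self, default_model):
        cases = [
            CaseRecord(id=f"c{i}", evidence=Evidence({}), labels={"fracture": 0})
            for i in range(3)
        ]
        results = predictive_validation(default_model, cases)
        assert results["fracture"].auc is None

    def test_empty_case_list_rejected(self, default_model):
        with pytest.raises(ValueError):
            predictive_validation(default_model, [])


def test_framework_registry_counts():
    summary = framework_summary()
    assert summary["total"] == 7
    assert summary["implemented"] == 4
    assert set(summary["deferred_domains"]) == {"concurrent", "convergent", "discriminant"}
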