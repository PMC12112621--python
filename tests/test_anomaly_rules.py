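"""Erythrocyte shape rule engine and leukocyte anomaly flags."""

import numpy as np
import pytest

from hemamorph.anomaly_rules import (
    RBC_SHAPE_LABELS,
    RuleConfig,
    anomaly_survey,
    build_rule_table,
    classify_rbc_shape,
    flag_wbc_anomaly,
)
from hemamorph.morphometry import REGISTRY, MorphometryVector
from hemamorph.synthetic_smear import RBC_ARCHETYPES, render_single_cell
from hemamorph.morphometry import extract_descriptors


def make_vector(**overrides) -> MorphometryVector:
    """A complete vector for a plain normal discocyte, with overrides.

    Geometric overrides: diameter_um sets cell_area; everything else maps
    directly to registry names or extras.
    """
    values = {n: 0.0 for n in REGISTRY.names}
    diameter = overrides.pop("diameter_um", 7.0)
    values["cell_area"] = np.pi * (diameter / 2) ** 2
    values["circularity"] = overrides.pop("circularity", 0.95)
    values["eccentricity"] = overrides.pop("eccentricity", 0.1)
    values["aspect_ratio"] = overrides.pop("aspect_ratio", 1.05)
    values["solidity"] = overrides.pop("solidity", 0.98)
    values["edge_gradient"] = overrides.pop("edge_gradient", 0.02)
    extras = {
        "inclusion_count": 0,
        "inclusions": [],
        "max_inclusion_eccentricity": 0.0,
        "has_peripheral_inclusion": False,
        "pallor_ratio": 0.25,
        "pallor_eccentricity": 0.2,
        "radial_inversions": 1,
        "interior_intensity": 0.6,
    }
    extras.update(overrides)
    return MorphometryVector(values, extras)


class TestRuleTable:
    def test_fifteen_labels_unique_priorities(self):
        table = build_rule_table()
        assert len(table) == 15
        assert {r.label for r in table} == set(RBC_SHAPE_LABELS)
        assert len({r.priority for r in table}) == 15

    def test_totality_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            v = make_vector(
                diameter_um=rng.uniform(2, 12),
                circularity=rng.uniform(0.3, 1.0),
                eccentricity=rng.uniform(0, 0.99),
                aspect_ratio=rng.uniform(1, 5),
                solidity=rng.uniform(0.5, 1.0),
                pallor_ratio=rng.uniform(0, 0.6),
                pallor_eccentricity=rng.uniform(0, 0.95),
                radial_inversions=int(rng.integers(0, 4)),
                interior_intensity=rng.uniform(0.2, 0.9),
                inclusion_count=int(rng.integers(0, 3)),
            )
            call = classify_rbc_shape(v)
            assert call.label in RBC_SHAPE_LABELS


class TestPublishedCriteria:
    def test_normal_discocyte(self):
        call = classify_rbc_shape(make_vector(diameter_um=7.0, circularity=0.95, eccentricity=0.2))
        assert call.label == "Normal"

    def test_elliptocyte_eccentricity_over_half(self):
        call = classify_rbc_shape(make_vector(eccentricity=0.6, circularity=0.8))
        assert call.label == "Elliptocyte"

    def test_stomatocyte_low_circularity_slit_pallor(self):
        call = classify_rbc_shape(
            make_vector(circularity=0.65, eccentricity=0.3, pallor_ratio=0.1, pallor_eccentricity=0.85)
        )
        assert call.label == "Stomatocyte"

    def test_macrocyte_diameter(self):
        call = classify_rbc_shape(make_vector(diameter_um=9.5, circularity=0.93))
        assert call.label == "Macrocyte"

    def test_inclusion_beats_normal_size(self):
        """A Howell–Jolly body on an otherwise normal cell wins over Normal."""
        call = classify_rbc_shape(
            make_vector(inclusion_count=1, inclusions=[{"size_px": 40}])
        )
        assert call.label == "Howell-Jolly"

    def test_measured_values_copied(self):
        call = classify_rbc_shape(make_vector(diameter_um=7.0))
        assert call.measured["diameter_um"] == pytest.approx(7.0)
        assert "circularity" in call.measured and "pallor_ratio" in call.measured

    def test_incomplete_vector_rejected(self):
        v = make_vector()
        del v.extras["pallor_ratio"]
        with pytest.raises(ValueError, match="pallor_ratio"):
            classify_rbc_shape(v)


class TestMonotonicity:
    def test_increasing_eccentricity_never_returns_to_normal(self):
        seen_abnormal = False
        for ecc in np.linspace(0.0, 0.99, 34):
            label = classify_rbc_shape(make_vector(eccentricity=float(ecc))).label
            if label != "Normal":
                seen_abnormal = True
            else:
                assert not seen_abnormal, f"Normal reappeared at ecc={ecc}"


class TestWbcFlag:
    def test_eccentricity_above_threshold_flags(self):
        flagged, why = flag_wbc_anomaly(make_vector(eccentricity=0.85), "lymphocyte")
        assert flagged and "eccentricity" in why[0]

    def test_boundary_is_strict(self):
        flagged, _ = flag_wbc_anomaly(make_vector(eccentricity=0.8), "lymphocyte")
        assert not flagged

    def test_low_eccentricity_low_gradient_not_flagged(self):
        flagged, _ = flag_wbc_anomaly(
            make_vector(eccentricity=0.1), "neutrophil", gradient_threshold=0.5
        )
        assert not flagged

    def test_gradient_condition_fires(self):
        flagged, why = flag_wbc_anomaly(
            make_vector(eccentricity=0.1, edge_gradient=0.9),
            "monocyte",
            gradient_threshold=0.5,
        )
        assert flagged and "gradient" in why[0]

    def test_non_wbc_rejected(self):
        with pytest.raises(ValueError):
            flag_wbc_anomaly(make_vector(), "rbc")


class TestSurvey:
    def test_all_archetypes_recovered_on_seeded_exemplars(self, cal):
        """Rule-engine recall on rendered exemplars of all 15 types."""
        truths, labels = [], []
        for i, arch in enumerate(RBC_ARCHETYPES):
            for j in range(3):
                sample, _ = render_single_cell(arch, cal, seed=1000 * i + j)
                inst = sample.instances[0]
                v = extract_descriptors(
                    sample.image, inst.mask, np.zeros_like(inst.mask), cal
                )
                truths.append(arch)
                labels.append(classify_rbc_shape(v))
        survey = anomaly_survey(truths, labels)
        assert sum(1 for c in survey.counts.values() if c > 0) == 15
        assert survey.accuracy >= 0.95

    def test_perfect_calls_give_accuracy_one(self):
        truths = list(RBC_SHAPE_LABELS)
        survey = anomaly_survey(truths, truths)
        assert survey.accuracy == 1.0
        assert all(survey.per_type_recall[l] == 1.0 for l in RBC_SHAPE_LABELS)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            anomaly_survey(["Normal"], [])
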