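"""Geometric anomaly rules for erythrocyte shapes and leukocyte activity.

Each red cell is assigned exactly one of 15 shape labels by an ordered
rule table over its morphometric vector.  Published criteria anchor the
table (elliptocyte: eccentricity > 0.5; stomatocyte: circularity < 0.7;
normal: diameter 6–8 µm with circularity > 0.9); the remaining thresholds
are explicit, documented defaults kept in an editable config.  Rule
precedence runs inclusion-based rules, then size rules, then shape rules,
with Normal second-to-last and the irregular catch-all (Pikilocyte) last,
so a cell with a Howell–Jolly body of otherwise normal geometry is never
labeled Normal.

All comparisons at thresholds are strict, matching the printed ">"/"<"
forms (a leukocyte with eccentricity exactly 0.8 is not flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import math

import numpy as np

from .io_formats import LabelSchema
from .morphometry import MorphometryVector
from .synthetic_smear import RBC_ARCHETYPES

RBC_SHAPE_LABELS: tuple[str, ...] = RBC_ARCHETYPES  # 15 labels incl. Normal


@dataclass
class RuleConfig:
    """Tunable thresholds of the rule table (units: µm, µm², dimensionless)."""

    normal_diameter: tuple[float, float] = (6.0, 8.0)
    normal_circularity_min: float = 0.9
    normal_pallor_band: tuple[float, float] = (0.05, 0.45)
    macrocyte_diameter_min: float = 8.5
    microcyte_diameter_max: float = 6.0
    microcyte_circularity_min: float = 0.9
    oval_ecc_band: tuple[float, float] = (0.35, 0.5)
    elliptocyte_ecc_min: float = 0.5
    pencil_ecc_min: float = 0.85
    pencil_aspect_min: float = 3.0
    normal_rbc_area_um2: float = math.pi * 3.5**2   # 7 µm discocyte
    fragment_area_fraction: float = 0.5
    fragment_solidity_max: float = 0.85
    target_inversions_min: int = 2
    inclusion_ecc_min: float = 0.8       # Hemoglobin-C crystal elongation
    peripheral_rim_depth: float = 0.15   # Heinz rim-contact band
    hyperchromic_intensity_max: float = 0.45
    stomatocyte_circularity_max: float = 0.7
    stomatocyte_pallor_ecc_min: float = 0.7
    wbc_ecc_flag: float = 0.8
    wbc_gradient_quantile: float = 0.95


@dataclass(frozen=True)
class AnomalyCall:
    """Rule-engine verdict for one red cell."""

    label: str
    rule_id: str
    measured: dict[str, float]


@dataclass(frozen=True)
class Rule:
    label: str
    rule_id: str
    predicate: Callable[[dict], bool]
    priority: int


_REQUIRED_EXTRAS = (
    "inclusion_count",
    "inclusions",
    "max_inclusion_eccentricity",
    "has_peripheral_inclusion",
    "pallor_ratio",
    "pallor_eccentricity",
    "radial_inversions",
    "interior_intensity",
)


def _evidence(v: MorphometryVector) -> dict:
    missing = [k for k in _REQUIRED_EXTRAS if k not in v.extras]
    if missing:
        raise ValueError(f"vector lacks rule evidence: {missing}")
    return {
        "diameter_um": v.equivalent_diameter,
        "area_um2": v["cell_area"],
        "circularity": v["circularity"],
        "eccentricity": v["eccentricity"],
        "aspect_ratio": v["aspect_ratio"],
        "solidity": v["solidity"],
        **{k: v.extras[k] for k in _REQUIRED_EXTRAS},
    }


def build_rule_table(config: RuleConfig | None = None) -> list[Rule]:
    """The ordered 15-label rule table (priority 0 fires first)."""
    c = config or RuleConfig()

    def normal_pallor(e):
        lo, hi = c.normal_pallor_band
        return lo <= e["pallor_ratio"] <= hi

    rules: list[tuple[str, str, Callable[[dict], bool]]] = [
        # inclusion-based rules
        (
            "Hemoglobin-C",
            "hbc_crystal",
            lambda e: e["inclusion_count"] >= 1
            and e["max_inclusion_eccentricity"] > c.inclusion_ecc_min,
        ),
        (
            "Heinz bodies",
            "heinz_peripheral_inclusion",
            lambda e: e["inclusion_count"] >= 1 and e["has_peripheral_inclusion"],
        ),
        (
            "Howell-Jolly",
            "howell_jolly_single_inclusion",
            lambda e: e["inclusion_count"] == 1,
        ),
        # pallor-profile rule
        (
            "Target",
            "target_radial_inversions",
            lambda e: e["radial_inversions"] >= c.target_inversions_min,
        ),
        # size rules
        (
            "Fragments",
            "fragment_small_irregular",
            lambda e: e["area_um2"] < c.fragment_area_fraction * c.normal_rbc_area_um2
            and e["solidity"] < c.fragment_solidity_max,
        ),
        (
            "Macrocyte",
            "macrocyte_diameter",
            lambda e: e["diameter_um"] > c.macrocyte_diameter_min,
        ),
        (
            "Microcircle",
            "microcircle_diameter",
            lambda e: e["diameter_um"] < c.microcyte_diameter_max
            and e["circularity"] > c.microcyte_circularity_min,
        ),
        # shape rules
        (
            "Pencil",
            "pencil_extreme_elongation",
            lambda e: e["eccentricity"] > c.pencil_ecc_min
            and e["aspect_ratio"] > c.pencil_aspect_min,
        ),
        (
            "Elliptocyte",
            "elliptocyte_eccentricity",
            lambda e: e["eccentricity"] > c.elliptocyte_ecc_min,
        ),
        (
            "Oval",
            "oval_moderate_eccentricity",
            lambda e: c.oval_ecc_band[0] < e["eccentricity"] <= c.oval_ecc_band[1],
        ),
        (
            "Stomatocyte",
            "stomatocyte_low_circularity_slit",
            lambda e: e["circularity"] < c.stomatocyte_circularity_max
            and e["pallor_eccentricity"] > c.stomatocyte_pallor_ecc_min,
        ),
        (
            "Hyperchromasia",
            "hyperchromic_dense_no_pallor",
            lambda e: e["interior_intensity"] < c.hyperchromic_intensity_max
            and e["pallor_ratio"] < c.normal_pallor_band[0],
        ),
        (
            "Spleen",
            "spherocytic_no_pallor",
            lambda e: e["pallor_ratio"] < c.normal_pallor_band[0]
            and e["circularity"] > c.normal_circularity_min
            and e["diameter_um"] <= c.macrocyte_diameter_min,
        ),
        (
            "Normal",
            "normal_discocyte",
            lambda e: c.normal_diameter[0] <= e["diameter_um"] <= c.normal_diameter[1]
            and e["circularity"] > c.normal_circularity_min
            and e["inclusion_count"] == 0
            and normal_pallor(e),
        ),
        # irregular catch-all guarantees totality
        ("Pikilocyte", "irregular_catch_all", lambda e: True),
    ]
    table = [Rule(lbl, rid, pred, prio) for prio, (lbl, rid, pred) in enumerate(rules)]
    assert len({r.label for r in table}) == 15
    return table


def classify_rbc_shape(
    v: MorphometryVector, config: RuleConfig | None = None
) -> AnomalyCall:
    """First matching rule in priority order wins; always returns a label."""
    evidence = _evidence(v)
    for rule in build_rule_table(config):
        if rule.predicate(evidence):
            measured = {
                k: evidence[k]
                for k in (
                    "diameter_um",
                    "circularity",
                    "eccentricity",
                    "aspect_ratio",
                    "solidity",
                    "pallor_ratio",
                    "pallor_eccentricity",
                    "inclusion_count",
                    "radial_inversions",
                    "interior_intensity",
                )
            }
            return AnomalyCall(rule.label, rule.rule_id, measured)
    raise AssertionError("rule table is total; unreachable")  # pragma: no cover


WBC_CLASSES = frozenset(
    {"basophil", "eosinophil", "lymphocyte", "monocyte", "myelocyte", "neutrophil"}
)


def flag_wbc_anomaly(
    v: MorphometryVector,
    class_name: str,
    config: RuleConfig | None = None,
    gradient_threshold: float | None = None,
) -> tuple[bool, list[str]]:
    """Flag a leukocyte as anomalous; returns (flag, evidence list).

    Fires on eccentricity strictly above 0.8, or on a boundary
    intensity-gradient score above its configured threshold (by default
    the 95th-percentile score is taken as the calibration threshold and
    must be supplied from a reference population; when absent only the
    eccentricity condition applies).
    """
    if class_name not in WBC_CLASSES:
        raise ValueError(f"{class_name!r} is not a leukocyte class")
    c = config or RuleConfig()
    evidence: list[str] = []
    if v["eccentricity"] > c.wbc_ecc_flag:
        evidence.append(f"eccentricity {v['eccentricity']:.3f} > {c.wbc_ecc_flag}")
    if gradient_threshold is not None and v["edge_gradient"] > gradient_threshold:
        evidence.append(
            f"boundary gradient {v['edge_gradient']:.4f} > {gradient_threshold:.4f}"
        )
    return bool(evidence), evidence


@dataclass
class SurveyResult:
    counts: dict[str, int]
    confusion: dict[str, dict[str, int]]
    per_type_recall: dict[str, float]
    per_type_precision: dict[str, float]
    accuracy: float
    n: int


def anomaly_survey(
    truths: list[str], calls: list[AnomalyCall | str]
) -> SurveyResult:
    """Per-type precision/recall and overall accuracy against known archetypes."""
    if len(truths) != len(calls):
        raise ValueError("length mismatch")
    preds = [c.label if isinstance(c, AnomalyCall) else c for c in calls]
    labels = list(RBC_SHAPE_LABELS)
    confusion = {t: {p: 0 for p in labels} for t in labels}
    for t, p in zip(truths, preds):
        confusion[t][p] += 1
    counts = {lbl: preds.count(lbl) for lbl in labels}
    recall, precision = {}, {}
    for lbl in labels:
        n_true = sum(confusion[lbl].values())
        n_pred = sum(confusion[t][lbl] for t in labels)
        tp = confusion[lbl][lbl]
        recall[lbl] = tp / n_true if n_true else float("nan")
        precision[lbl] = tp / n_pred if n_pred else float("nan")
    acc = sum(confusion[lbl][lbl] for lbl in labels) / len(truths)
    return SurveyResult(counts, confusion, recall, precision, acc, len(truths))


def rule_table_summary(config: RuleConfig | None = None) -> list[dict]:
    """Human-editable view of the rule table (label, id, priority, params)."""
    cfg = asdict(config or RuleConfig())
    return [
        {"priority": r.priority, "label": r.label, "rule_id": r.rule_id}
        for r in build_rule_table(config)
    ] + [{"config": cfg}]
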