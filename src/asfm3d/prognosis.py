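"""Prognostic formulas, recovery classification, ROC/cutoff analysis.

The prognostic layer predicts the final Sunnybrook (SFGS) score of an acute
facial-palsy patient from earlier measurements:

* first month after onset — from the ENoG degeneration rate x (%):
  ``y = 132.112 − 0.699·x``;
* second month — from the second-visit SFGS score x1 and the simultaneous
  gross 3D facial-motion score x2: ``y = 13.457 + 0.384·x1 + 0.823·x2``.

Recovery is dichotomized as good when the final SFGS is ≥ 70, or the final
House-Brackmann grade is ≤ II. Discrimination of poor recovery by a
continuous predictor is quantified by an empirical ROC curve with trapezoid
AUC, a stratified-bootstrap 95% CI, and a Youden-optimal cutoff. Study-level
cutoffs (e.g., a gross facial-motion score < 31 at the first visit or < 49
at the second predicting poor recovery) ship as packaged constants — they
are study-derived and cannot be re-derived without the patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .io import ClinicalRecord
from .landmarks import HBGrade

# ---------------------------------------------------------------------------
# Prediction formulas and recovery criteria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearPrognosticModel:
    """y = intercept + Σ coefficients[name]·x[name]."""

    intercept: float
    coefficients: dict[str, float]
    outcome_name: str = "final_sfgs"
    r_squared: float | None = None
    p_values: dict[str, float] | None = None

    def __post_init__(self):
        if not self.coefficients:
            raise ValidationError("model needs at least one predictor")

    def predict(self, **predictors: float) -> float:
        missing = set(self.coefficients) - set(predictors)
        if missing:
            raise ValidationError(f"missing predictors: {sorted(missing)}")
        return self.intercept + sum(
            self.coefficients[k] * float(predictors[k]) for k in self.coefficients
        )


#: first-visit model: final SFGS from the ENoG degeneration rate (%)
MONTH1_MODEL = LinearPrognosticModel(
    intercept=132.112, coefficients={"enog_degeneration": -0.699}
)
#: second-visit model: final SFGS from second-visit SFGS and gross motion score
MONTH2_MODEL = LinearPrognosticModel(
    intercept=13.457, coefficients={"sfgs2": 0.384, "asfm2": 0.823}
)


@dataclass(frozen=True)
class Prediction:
    raw: float
    clamped: float


def _check_0_100(name: str, value: float) -> None:
    if not 0 <= value <= 100:
        raise ValidationError(f"{name} must lie in [0,100], got {value}")


def predict_month1(enog_degeneration: float) -> Prediction:
    """Predicted final SFGS from the first-month ENoG degeneration rate."""
    _check_0_100("ENoG degeneration", enog_degeneration)
    raw = MONTH1_MODEL.predict(enog_degeneration=enog_degeneration)
    return Prediction(raw=raw, clamped=min(100.0, max(0.0, raw)))


def predict_month2(sfgs2: float, asfm2: float) -> Prediction:
    """Predicted final SFGS from second-month SFGS and gross motion score."""
    _check_0_100("second-visit SFGS", sfgs2)
    _check_0_100("second-visit gross motion score", asfm2)
    raw = MONTH2_MODEL.predict(sfgs2=sfgs2, asfm2=asfm2)
    return Prediction(raw=raw, clamped=min(100.0, max(0.0, raw)))


@dataclass(frozen=True)
class RecoveryCriteria:
    """Good recovery: final SFGS ≥ 70, or final House-Brackmann grade ≤ II."""

    sfgs_good_threshold: float = 70.0
    hbgs_good_max_grade: HBGrade = HBGrade.II


def classify_recovery(
    record: ClinicalRecord, criteria: RecoveryCriteria = RecoveryCriteria()
) -> dict[str, str]:
    """{'sfgs': good|poor, 'hbgs': good|poor} for whichever outcomes exist."""
    if record.sfgs is None and record.hbgs is None:
        raise ValidationError(
            f"patient {record.patient_id}: neither SFGS nor H-B grade available"
        )
    out: dict[str, str] = {}
    if record.sfgs is not None:
        out["sfgs"] = "good" if record.sfgs >= criteria.sfgs_good_threshold else "poor"
    if record.hbgs is not None:
        out["hbgs"] = "good" if record.hbgs <= criteria.hbgs_good_max_grade else "poor"
    return out


# ---------------------------------------------------------------------------
# Study cutoffs (packaged constants — derived from the original cohort)
# ---------------------------------------------------------------------------

HIGHER_PREDICTS_POOR = "higher_predicts_poor"
LOWER_PREDICTS_POOR = "lower_predicts_poor"


@dataclass(frozen=True)
class StudyCutoff:
    measure: str
    visit: int
    cutoff: float
    direction: str
    specificity: float  # %
    sensitivity: float  # %
    auc: float


#: cutoffs against the SFGS-based recovery criterion (study-derived; not
#: re-derivable without the original 37-patient dataset)
SFGS_CRITERION_CUTOFFS = (
    StudyCutoff("enog", 1, 87, HIGHER_PREDICTS_POOR, 92, 84, 0.955),
    StudyCutoff("enog", 2, 80, HIGHER_PREDICTS_POOR, 92, 84, 0.910),
    StudyCutoff("sfgs", 1, 40, LOWER_PREDICTS_POOR, 100, 84, 0.903),
    StudyCutoff("sfgs", 2, 51, LOWER_PREDICTS_POOR, 100, 84, 0.908),
    StudyCutoff("asfm", 1, 31, LOWER_PREDICTS_POOR, 92, 80, 0.868),
    StudyCutoff("asfm", 2, 49, LOWER_PREDICTS_POOR, 83, 84, 0.893),
)

#: cutoffs against the House-Brackmann recovery criterion
HBGS_CRITERION_CUTOFFS = (
    StudyCutoff("enog", 1, 91, HIGHER_PREDICTS_POOR, 78, 90, 0.910),
    StudyCutoff("enog", 2, 80, HIGHER_PREDICTS_POOR, 89, 75, 0.845),
    StudyCutoff("sfgs", 1, 36, LOWER_PREDICTS_POOR, 78, 82, 0.849),
    StudyCutoff("sfgs", 2, 48.5, LOWER_PREDICTS_POOR, 89, 86, 0.879),
    StudyCutoff("asfm", 1, 31, LOWER_PREDICTS_POOR, 89, 71, 0.827),
    StudyCutoff("asfm", 2, 49, LOWER_PREDICTS_POOR, 89, 79, 0.897),
)


def get_cutoff(measure: str, visit: int, criterion: str = "sfgs") -> StudyCutoff:
    table = SFGS_CRITERION_CUTOFFS if criterion == "sfgs" else HBGS_CRITERION_CUTOFFS
    for c in table:
        if c.measure == measure and c.visit == visit:
            return c
    raise ValidationError(f"no packaged cutoff for {measure!r} visit {visit}")


def classify_by_cutoff(value: float, cutoff: StudyCutoff) -> str:
    """'poor' when the value falls on the poor side of the study cutoff."""
    if cutoff.direction == LOWER_PREDICTS_POOR:
        return "poor" if value < cutoff.cutoff else "good"
    return "poor" if value > cutoff.cutoff else "good"


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class RocAnalysis:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    chosen_cutoff: float
    direction: str
    n_positive: int
    n_negative: int

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "auc_class": auc_class(self.auc),
            "chosen_cutoff": self.chosen_cutoff,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "points": [
                {"threshold": float(t), "sensitivity": float(se), "specificity": float(sp)}
                for t, se, sp in zip(self.thresholds, self.sensitivity, self.specificity)
            ],
        }


def _roc_points(values: np.ndarray, positive: np.ndarray, direction: str):
    """Sensitivity/specificity at every distinct threshold.

    'positive' means the event being detected (poor recovery). For
    LOWER_PREDICTS_POOR a case is called positive when value < threshold;
    for HIGHER_PREDICTS_POOR when value > threshold.
    """
    thresholds = np.unique(values)
    # add sentinels so the curve reaches (0,0) and (1,1)
    pad = np.concatenate(([thresholds[0] - 1.0], thresholds, [thresholds[-1] + 1.0]))
    sens = np.empty(pad.size)
    spec = np.empty(pad.size)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    for i, th in enumerate(pad):
        called = values < th if direction == LOWER_PREDICTS_POOR else values > th
        sens[i] = (called & positive).sum() / n_pos
        spec[i] = (~called & ~positive).sum() / n_neg
    return pad, sens, spec


def _trapezoid_auc(sens: np.ndarray, spec: np.ndarray) -> float:
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(np.sort(sens[order]), np.sort(fpr[order])))


def roc(
    scores: list[tuple[float, str]],
    direction: str = LOWER_PREDICTS_POOR,
    *,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RocAnalysis:
    """Empirical ROC of a continuous value against a good/poor outcome.

    AUC by the trapezoid rule; its CI by stratified bootstrap (resampling
    cases within each outcome class, seeded). The reported cutoff maximizes
    the Youden index sensitivity + specificity − 1, ties broken toward
    higher specificity, then toward the more conservative threshold.
    """
    if direction not in (LOWER_PREDICTS_POOR, HIGHER_PREDICTS_POOR):
        raise ValidationError(f"unknown ROC direction {direction!r}")
    values = np.array([float(v) for v, _ in scores])
    outcomes = [o for _, o in scores]
    if not set(outcomes) <= {"good", "poor"}:
        raise ValidationError("outcomes must be 'good' or 'poor'")
    positive = np.array([o == "poor" for o in outcomes])
    if positive.all() or not positive.any():
        raise ValidationError("ROC needs at least one case in each outcome class")

    thresholds, sens, spec = _roc_points(values, positive, direction)
    auc = _trapezoid_auc(sens, spec)

    j = sens + spec - 1.0
    best = np.lexsort((thresholds, -spec, -j))[0]
    chosen = float(thresholds[best])

    rng = np.random.default_rng(seed)
    pos_vals, neg_vals = values[positive], values[~positive]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        pv = rng.choice(pos_vals, size=pos_vals.size, replace=True)
        nv = rng.choice(neg_vals, size=neg_vals.size, replace=True)
        bv = np.concatenate([pv, nv])
        bp = np.concatenate([np.ones(pv.size, bool), np.zeros(nv.size, bool)])
        _, bs, bq = _roc_points(bv, bp, direction)
        boot[b] = _trapezoid_auc(bs, bq)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])

    return RocAnalysis(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=(float(lo), float(hi)),
        chosen_cutoff=chosen,
        direction=direction,
        n_positive=int(positive.sum()),
        n_negative=int((~positive).sum()),
    )


def auc_class(auc: float) -> str:
    """Discriminative-accuracy band: low 0.5–0.7, moderate 0.7–0.9, high >0.9."""
    if not 0 <= auc <= 1:
        raise ValidationError(f"AUC must lie in [0,1], got {auc}")
    if auc < 0.5:
        import logging

        logging.getLogger("asfm3d").warning(
            "AUC %.3f < 0.5: the predictor's direction is probably inverted", auc
        )
        return "low"
    if auc <= 0.7:
        return "low"
    if auc <= 0.9:
        return "moderate"
    return "high"


# ---------------------------------------------------------------------------
# Regression utilities
# ---------------------------------------------------------------------------


def green_min_n(r_squared: float, m: int) -> int:
    """Minimum subjects n ≥ 8(1−R²)/R² + (m−1) for m-predictor regression."""
    if not 0 < r_squared <= 1:
        raise ValidationError(f"R² must lie in (0,1], got {r_squared}")
    if m < 1:
        raise ValidationError(f"predictor count must be ≥1, got {m}")
    return math.ceil(8.0 * (1.0 - r_squared) / r_squared + (m - 1))


@dataclass(frozen=True)
class FitResult:
    model: LinearPrognosticModel
    r_squared: float
    conf_int: dict[str, tuple[float, float]]  # 95% CI per predictor + intercept


def fit_linear(outcome, predictors: pd.DataFrame, outcome_name: str = "outcome") -> FitResult:
    """Ordinary least squares with intercept; coefficients, R², p-values, CIs."""
    y = np.asarray(outcome, float)
    X = pd.DataFrame(predictors).astype(float)
    if len(y) != len(X):
        raise ValidationError("outcome and predictors disagree on length")
    if len(y) <= X.shape[1] + 1:
        raise ValidationError(
            f"need n > p+1 observations, got n={len(y)} for p={X.shape[1]}"
        )
    if np.isnan(y).any() or X.isna().any().any():
        raise ValidationError("missing cells are not allowed in a regression fit")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    model = LinearPrognosticModel(
        intercept=float(res.params["const"]),
        coefficients={c: float(res.params[c]) for c in X.columns},
        outcome_name=outcome_name,
        r_squared=float(res.rsquared),
        p_values={c: float(res.pvalues[c]) for c in X.columns},
    )
    return FitResult(
        model=model,
        r_squared=float(res.rsquared),
        conf_int={name: (float(ci.loc[name, 0]), float(ci.loc[name, 1])) for name in design.columns},
    )


def stepwise_select(
    outcome,
    candidates: pd.DataFrame,
    *,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    outcome_name: str = "outcome",
) -> LinearPrognosticModel | None:
    """Forward stepwise OLS with backward elimination.

    At each forward step the candidate with the smallest p-value below
    ``p_enter`` joins (ties by smaller p, then name); included predictors
    whose p-value rises above ``p_remove`` are dropped. Deterministic for a
    fixed input. Returns None when nothing enters.
    """
    y = np.asarray(outcome, float)
    X = pd.DataFrame(candidates).astype(float)
    if np.var(y) == 0:
        return None  # constant outcome: nothing to explain
    selected: list[str] = []
    remaining = list(X.columns)
    while True:
        best_name, best_p = None, p_enter
        for name in remaining:
            cols = selected + [name]
            try:
                fit = fit_linear(y, X[cols], outcome_name)
            except ValidationError:
                continue  # rank-deficient with this candidate (e.g., duplicate)
            p = fit.model.p_values[name]
            if p < best_p or (best_name is not None and p == best_p and name < best_name):
                best_name, best_p = name, p
        if best_name is None:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        # backward check
        while len(selected) > 1:
            fit = fit_linear(y, X[selected], outcome_name)
            worst = max(selected, key=lambda c: (fit.model.p_values[c], c))
            if fit.model.p_values[worst] > p_remove:
                selected.remove(worst)
                remaining.append(worst)
            else:
                break
    if not selected:
        return None
    return fit_linear(y, X[selected], outcome_name).model


# ---------------------------------------------------------------------------
# Cohort accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttritionSummary:
    enrolled: int
    excluded_before_followup: int
    eligible: int
    lost_to_followup: int
    analyzed: int
    loss_rate_percent: float


def attrition_summary(
    enrolled: int, excluded_before_followup: int, lost_to_followup: int
) -> AttritionSummary:
    """Cohort flow arithmetic: eligible n, analyzed n and loss-to-follow-up %."""
    if min(enrolled, excluded_before_followup, lost_to_followup) < 0:
        raise ValidationError("cohort counts must be non-negative")
    eligible = enrolled - excluded_before_followup
    if lost_to_followup > eligible or eligible <= 0:
        raise ValidationError("inconsistent cohort counts")
    return AttritionSummary(
        enrolled=enrolled,
        excluded_before_followup=excluded_before_followup,
        eligible=eligible,
        lost_to_followup=lost_to_followup,
        analyzed=eligible - lost_to_followup,
        loss_rate_percent=100.0 * lost_to_followup / eligible,
    )


def recovery_rate_percent(
    records: list[ClinicalRecord],
    criterion: str,
    criteria: RecoveryCriteria = RecoveryCriteria(),
) -> float:
    """Percent of records classified 'good' under one recovery criterion."""
    labels = [classify_recovery(r, criteria)[criterion] for r in records]
    return 100.0 * sum(l == "good" for l in labels) / len(labels)
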