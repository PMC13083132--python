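"""Effect-size-weighted composite score and ROC evaluation.

Inter-network features passing the FDR threshold are combined into a single
discriminant score per subject: the sum of each feature value times the
absolute Cohen's d of its group contrast.  Discrimination is summarised by
the Mann-Whitney rank AUC with a stratified percentile-bootstrap CI, and an
operating point chosen by the Youden index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .stats import fisher_exact_2x2
from .types import ValidationError


class NoModelError(ValueError):
    """Raised when no feature survives the FDR threshold."""


@dataclass
class CompositeModel:
    """|d|-weighted linear composite over FDR-significant features."""

    features: list[str]
    weights: np.ndarray
    contrast: str
    condition: str
    q_threshold: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.features) == 0:
            raise NoModelError("composite model needs at least one feature")
        if np.any(self.weights <= 0):
            raise ValidationError("composite weights must be positive")


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci: tuple[float, float] | None
    flipped: bool
    youden_threshold: float = field(default=np.nan)
    sensitivity: float = field(default=np.nan)
    specificity: float = field(default=np.nan)


def fit_composite(
    contrasts: pd.DataFrame,
    contrast: str = "SCZ:CON",
    condition: str = "1-back",
    q_threshold: float = 0.05,
    feature_class: str = "inter",
) -> CompositeModel:
    """Select FDR-significant inter-network features and weight them by |d|."""
    from .metrics import feature_class as classify

    sub = contrasts[
        (contrasts["contrast"] == contrast) & (contrasts["condition"] == condition)
    ]
    if feature_class is not None:
        sub = sub[[classify(f) == feature_class for f in sub["feature"]]]
    sig = sub[sub["q"] < q_threshold]
    if sig.empty:
        raise NoModelError(
            f"no {feature_class} feature with q < {q_threshold} for "
            f"{contrast} at {condition}"
        )
    return CompositeModel(
        features=list(sig["feature"]),
        weights=np.abs(sig["d"].to_numpy(dtype=float)),
        contrast=contrast,
        condition=condition,
        q_threshold=q_threshold,
    )


def score(model: CompositeModel, features: pd.DataFrame) -> pd.Series:
    """Composite score per row: sum_j value_ij * |d_j| on raw feature values."""
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise ValidationError(f"features missing from table: {missing}")
    vals = features[model.features].to_numpy(dtype=float)
    s = vals @ model.weights
    index = (
        features["subject_id"] if "subject_id" in features.columns else features.index
    )
    return pd.Series(s, index=index, name="composite_score")


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC estimator with midrank tie handling.

    Estimates P(score_pos > score_neg) + 0.5 P(equal) for labels in {0, 1}.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("rank_auc needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> RocResult:
    """ROC curve, rank AUC, bootstrap CI and Youden operating point.

    Orientation is chosen so the reported AUC is >= 0.5; ``flipped`` records
    whether scores were negated.  The CI is a stratified percentile
    bootstrap (resampling within each class); pass ``n_boot=0`` to skip it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc0 = rank_auc(scores, labels)
    flipped = auc0 < 0.5
    oriented = -scores if flipped else scores
    auc = 1 - auc0 if flipped else auc0

    fpr, tpr, thr = roc_curve(labels, oriented)
    ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        pos = oriented[labels == 1]
        neg = oriented[labels == 0]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            boots[b] = rank_auc(
                np.concatenate([bp, bn]),
                np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)]),
            )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(lo), float(hi))

    result = RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(auc),
                       auc_ci=ci, flipped=bool(flipped))
    thr_y, sens, spec = youden(result)
    result.youden_threshold, result.sensitivity, result.specificity = thr_y, sens, spec
    return result


def youden(r: RocResult) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity - 1.

    Ties are broken toward higher specificity (lower false-positive rate);
    ``roc_curve`` orders points by increasing FPR, so the first maximum wins.
    """
    j = r.tpr - r.fpr
    i = int(np.argmax(j))
    return float(r.thresholds[i]), float(r.tpr[i]), float(1 - r.fpr[i])


@dataclass
class MisclassificationProfile:
    crosstab: pd.DataFrame
    fisher_p: float | None
    note: str
    clinical_means: pd.DataFrame


def misclassification_profile(
    scores: np.ndarray,
    labels: np.ndarray,
    roc_result: RocResult,
    metadata: pd.DataFrame,
    focal_subtype: int | str,
    clinical_columns: list[str] | None = None,
) -> MisclassificationProfile:
    """Characterize misclassified positive-class subjects (e.g. patients).

    Cross-tabulates misclassified vs correctly classified patients by
    membership in ``focal_subtype`` (metadata column ``subtype``) and tests
    the association with Fisher's exact test; also reports mean values of
    the named clinical columns in each set.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    oriented = -scores if roc_result.flipped else scores
    predicted = (oriented >= roc_result.youden_threshold).astype(int)

    patients = labels == 1
    miss = patients & (predicted == 0)
    correct = patients & (predicted == 1)
    meta = metadata.reset_index(drop=True)
    in_focal = (meta["subtype"] == focal_subtype).to_numpy()

    tab = pd.DataFrame(
        {
            "focal_subtype": [int((miss & in_focal).sum()), int((correct & in_focal).sum())],
            "other": [int((miss & ~in_focal).sum()), int((correct & ~in_focal).sum())],
        },
        index=["misclassified", "correct"],
    )
    try:
        p: float | None = fisher_exact_2x2(tab.to_numpy())
        note = ""
    except ValidationError:
        p = None
        note = "not applicable (degenerate margin)"

    if clinical_columns is None:
        clinical_columns = []
    means = pd.DataFrame(
        {
            "misclassified": meta.loc[miss, clinical_columns].mean()
            if clinical_columns else pd.Series(dtype=float),
            "correct": meta.loc[correct, clinical_columns].mean()
            if clinical_columns else pd.Series(dtype=float),
        }
    )
    return MisclassificationProfile(crosstab=tab, fisher_p=p, note=note, clinical_means=means)
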