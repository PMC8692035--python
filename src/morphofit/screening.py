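"""Screening models: predict device size from physical-exam features.

Eight features measurable without CT — age, sex, BMI and five anatomical
distances (ASIS–ASIS, xiphoid–pubis, body depth, width, circumference) —
predict the average area of the maximal fitted device per shape.

Two model families, both 10-fold cross-validated with pooled out-of-fold
metrics:

* regression — support-vector regression with a degree-2 polynomial
  kernel ("quadratic SVM"); features are z-scored and the response is
  z-scored inside each training fold (box constraint 1 is therefore in
  units of the response SD), ε set by the IQR/13.49 heuristic;
* classification into quartile bands of the response (<25th, 25–49th,
  50–74th, ≥75th percentile) — Gaussian-kernel SVM with the named kernel
  scale presets medium = √p and coarse = 4√p on standardized features.

Patients missing any of the eight features are excluded up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .io import PatientRecord

__all__ = [
    "FEATURE_NAMES",
    "assemble_features",
    "cross_validated_regression",
    "percentile_bands",
    "cross_validated_classifier",
    "RegressionReport",
    "ClassificationReport",
]

FEATURE_NAMES = ("age", "sex", "bmi", "asis_distance",
                 "xiphoid_pubis_distance", "body_depth", "body_width",
                 "body_circumference")

KERNEL_SCALE_FACTORS = {"medium": 1.0, "coarse": 4.0}  # × √p


@dataclass(frozen=True)
class RegressionReport:
    shape: str
    n_patients: int
    r_squared: float
    rmse: float
    mae: float
    predictions: np.ndarray  # pooled out-of-fold, patient order
    patient_ids: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"shape": self.shape, "n_patients": self.n_patients,
                "r_squared": self.r_squared, "rmse_mm2": self.rmse,
                "mae_mm2": self.mae}


@dataclass(frozen=True)
class ClassificationReport:
    shape: str
    n_patients: int
    class_edges: tuple[float, float, float]
    confusion: np.ndarray          # (4, 4) rows = true class
    accuracy: float
    roc_curves: dict = field(default_factory=dict)
    # per class: {"fpr": ..., "tpr": ..., "auc": ..., "operating_point": (fpr, tpr)}

    def to_dict(self) -> dict:
        return {"shape": self.shape, "n_patients": self.n_patients,
                "class_edges": list(self.class_edges),
                "confusion": self.confusion.tolist(),
                "accuracy": self.accuracy,
                "auc_per_class": {k: v["auc"]
                                  for k, v in self.roc_curves.items()}}


def assemble_features(cohort: list[PatientRecord]
                      ) -> tuple[pd.DataFrame, list[tuple[str, tuple[str, ...]]]]:
    """Complete-case feature matrix and the exclusion list with reasons.

    Sex is encoded female→0, male→1. Requires at least 10 complete cases
    (one per cross-validation fold).
    """
    rows, excluded = [], []
    for r in cohort:
        missing = r.missing_fields
        if missing:
            excluded.append((r.patient_id, missing))
            continue
        rows.append({"patient_id": r.patient_id, "age": r.age,
                     "sex": 0.0 if r.sex == "female" else 1.0, "bmi": r.bmi,
                     "asis_distance": r.asis_distance,
                     "xiphoid_pubis_distance": r.xiphoid_pubis_distance,
                     "body_depth": r.body_depth, "body_width": r.body_width,
                     "body_circumference": r.body_circumference})
    if len(rows) < 10:
        raise ValueError(
            f"only {len(rows)} complete-feature patients; need >= 10 for "
            "10-fold cross-validation")
    df = pd.DataFrame(rows).set_index("patient_id")
    return df[list(FEATURE_NAMES)], excluded


def cross_validated_regression(features: pd.DataFrame | np.ndarray,
                               response: np.ndarray, folds: int = 10,
                               seed: int = 0, shape: str = "",
                               degree: int = 2, C: float = 1.0,
                               ) -> RegressionReport:
    """Quadratic-kernel SVR with k-fold CV and pooled out-of-fold metrics.

    Standardization statistics (features and response) come from each
    training fold only — no information leaks from the held-out fold.
    R² = 1 − SSE/SST on pooled out-of-fold predictions; RMSE/MAE in the
    response's own units.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(response, dtype=float)
    ids = (tuple(features.index) if isinstance(features, pd.DataFrame)
           else tuple(str(i) for i in range(len(y))))
    if len(X) < folds:
        raise ValueError(f"need at least {folds} cases for {folds}-fold CV")
    if np.std(y) < 1e-12:
        raise ValueError("degenerate response: zero variance")
    p = X.shape[1]
    oof = np.empty(len(y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        xsc = StandardScaler().fit(X[train])
        ymu, ysd = y[train].mean(), y[train].std()
        yt = (y[train] - ymu) / ysd
        q75, q25 = np.percentile(yt, [75, 25])
        eps = max((q75 - q25) / 13.49, 1e-6)
        model = SVR(kernel="poly", degree=degree, gamma=1.0 / p, coef0=1.0,
                    C=C, epsilon=eps)
        model.fit(xsc.transform(X[train]), yt)
        oof[test] = model.predict(xsc.transform(X[test])) * ysd + ymu
    sse = float(np.sum((y - oof) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return RegressionReport(
        shape=shape, n_patients=len(y), r_squared=1 - sse / sst,
        rmse=float(np.sqrt(sse / len(y))),
        mae=float(np.mean(np.abs(y - oof))),
        predictions=oof, patient_ids=ids)


def percentile_bands(responses: np.ndarray
                     ) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Quartile-band labels 0–3 with edges at the 25/50/75th percentiles.

    Percentiles use the linear-interpolation definition. Bands are
    half-open below each edge: a value equal to an edge belongs to the
    band above it (so the ≥75th band is closed at its lower edge).
    """
    y = np.asarray(responses, dtype=float)
    if len(np.unique(y)) < 4:
        raise ValueError("need >= 4 distinct response values for quartile bands")
    edges = np.percentile(y, [25, 50, 75])
    if not (edges[0] < edges[1] < edges[2]):
        raise ValueError("degenerate quartile edges (heavy ties)")
    labels = np.searchsorted(edges, y, side="right")
    return labels, (float(edges[0]), float(edges[1]), float(edges[2]))


def cross_validated_classifier(features: pd.DataFrame | np.ndarray,
                               labels: np.ndarray,
                               kernel_scale: str = "medium",
                               folds: int = 10, seed: int = 0,
                               shape: str = "", C: float = 1.0,
                               n_classes: int = 4) -> ClassificationReport:
    """Gaussian-kernel SVM over quartile bands with stratified k-fold CV.

    Kernel scale presets on standardized features: medium = √p,
    coarse = 4√p (γ = 1/scale²). ROC curves are one-vs-rest on pooled
    out-of-fold decision values; the operating point is the hard
    classifier's (FPR, TPR) per class.
    """
    if kernel_scale not in KERNEL_SCALE_FACTORS:
        raise ValueError(f"kernel_scale must be one of {tuple(KERNEL_SCALE_FACTORS)}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < folds:
        raise ValueError(
            f"stratified {folds}-fold impossible: smallest class has "
            f"{min(counts.values())} members")
    p = X.shape[1]
    scale = KERNEL_SCALE_FACTORS[kernel_scale] * np.sqrt(p)
    gamma = 1.0 / scale ** 2
    pred = np.empty(len(y), dtype=y.dtype)
    dec = np.full((len(y), len(classes)), np.nan)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        xsc = StandardScaler().fit(X[train])
        model = SVC(kernel="rbf", gamma=gamma, C=C,
                    decision_function_shape="ovr")
        model.fit(xsc.transform(X[train]), y[train])
        Xt = xsc.transform(X[test])
        pred[test] = model.predict(Xt)
        d = model.decision_function(Xt)
        if d.ndim == 1:  # binary: single margin column
            d = np.column_stack([-d, d])
        # align fold's class order with the global class order
        col = {c: j for j, c in enumerate(model.classes_)}
        for gj, c in enumerate(classes):
            if c in col:
                dec[test, gj] = d[:, col[c]]
    cm = confusion_matrix(y, pred, labels=classes)
    acc = float((pred == y).mean())
    roc: dict = {}
    for gj, c in enumerate(classes):
        truth = (y == c).astype(int)
        score = dec[:, gj]
        ok = ~np.isnan(score)
        fpr, tpr, _ = roc_curve(truth[ok], score[ok])
        hard_tpr = float(((pred == c) & (y == c)).sum() / max((y == c).sum(), 1))
        hard_fpr = float(((pred == c) & (y != c)).sum() / max((y != c).sum(), 1))
        roc[str(c)] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr)),
                       "operating_point": (hard_fpr, hard_tpr)}
    edges = (float("nan"),) * 3
    return ClassificationReport(shape=shape, n_patients=len(y),
                                class_edges=edges, confusion=cm,
                                accuracy=acc, roc_curves=roc)
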