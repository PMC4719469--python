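"""Workload classification from per-optode peak responses.

Each trial is summarized by its 16-optode vector of ΔHbO2 peak
responses and labelled by load level (high vs. low).  Per subject,
trials are split into 10 stratified folds; each fold is predicted by
a linear maximum-margin classifier (SVM, C = 1) trained on the other
nine, with features standardized using training-fold statistics only.
Accuracy (overall), sensitivity (recall on high-load trials) and
specificity (recall on low-load trials) are computed per subject from
the pooled out-of-fold confusion matrix and then averaged across
subjects.  Everything is reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

__all__ = ["ClassificationReport", "trial_matrix", "crossval_classify", "compare_filters"]


@dataclass(frozen=True)
class ClassificationReport:
    """Cross-validated metrics, one row per subject plus the means."""

    per_subject: pd.DataFrame = field(repr=False)
    folds: int = 10
    seed: int = 0
    high_label: object = "high"
    low_label: object = "low"

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_subject["accuracy"].mean())

    @property
    def mean_sensitivity(self) -> float:
        return float(self.per_subject["sensitivity"].mean())

    @property
    def mean_specificity(self) -> float:
        return float(self.per_subject["specificity"].mean())

    def to_csv(self, path: str | Path, filter_label: str = "") -> None:
        df = self.per_subject.copy()
        df.insert(1, "filter", filter_label)
        df["seed"] = self.seed
        df.to_csv(path, index=False)


def trial_matrix(
    features: pd.DataFrame,
    measure: str = "delta_hbo2",
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pivot tidy features into per-subject (X, labels) trial matrices.

    Rows are trials (identified by onset), columns optodes 1..16.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sid, sub in features.groupby("subject_id"):
        wide = sub.pivot_table(index="onset_s", columns="optode", values=measure)
        labels = sub.drop_duplicates("onset_s").set_index("onset_s")["level"]
        labels = labels.loc[wide.index]
        out[str(sid)] = (wide.to_numpy(dtype=float), labels.to_numpy())
    return out


def _confusion(y_true, y_pred, positive) -> tuple[int, int, int, int]:
    pos = y_true == positive
    pred_pos = y_pred == positive
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    return tp, tn, fp, fn


def crossval_classify(
    features: pd.DataFrame,
    high_label="high",
    low_label="low",
    folds: int = 10,
    seed: int = 0,
    measure: str = "delta_hbo2",
    C: float = 1.0,
) -> ClassificationReport:
    """Per-subject stratified k-fold linear-SVM classification.

    ``features`` is the tidy trial-feature table; the positive class
    for sensitivity is ``high_label``.  Trials with other labels
    (e.g. a middle load level) are excluded from the contrast.
    """
    features = features[features["level"].isin([high_label, low_label])]
    matrices = trial_matrix(features, measure)
    rows = []
    rng = np.random.default_rng(seed)
    for sid, (X, y) in matrices.items():
        present = set(np.unique(y))
        if not {high_label, low_label} <= present:
            raise ValueError(
                f"subject {sid}: both labels required, found {sorted(map(str, present))}"
            )
        if len(y) < folds:
            raise ValueError(
                f"subject {sid}: {len(y)} trials < {folds} folds"
            )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=sub_seed)
        y_pred = np.empty_like(y)
        for train, test in skf.split(X, y):
            clf = make_pipeline(
                StandardScaler(), SVC(kernel="linear", C=C)
            )
            clf.fit(X[train], y[train])
            y_pred[test] = clf.predict(X[test])
        tp, tn, fp, fn = _confusion(y, y_pred, high_label)
        rows.append({
            "subject_id": sid,
            "accuracy": (tp + tn) / (tp + tn + fp + fn),
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "n_trials": len(y),
        })
    return ClassificationReport(
        per_subject=pd.DataFrame(rows), folds=folds, seed=seed,
        high_label=high_label, low_label=low_label,
    )


def compare_filters(
    reports: dict[str, ClassificationReport],
    baseline: str = "chance",
    metric: str = "accuracy",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired comparisons of per-subject metrics between filters.

    All pairwise filter contrasts (paired t across subjects) plus, when
    ``baseline="chance"``, each filter against 0.5; p-values are
    Holm-corrected.  All reports must cover the same subjects.
    """
    names = list(reports)
    series = {}
    ref = None
    for name in names:
        s = reports[name].per_subject.set_index("subject_id")[metric].sort_index()
        if ref is None:
            ref = list(s.index)
        elif list(s.index) != ref:
            raise ValueError(f"report {name!r} covers different subjects")
        series[name] = s.to_numpy(dtype=float)

    def _paired_t(d):
        if np.std(d, ddof=1) == 0.0:
            # degenerate zero-variance contrast
            m = float(np.mean(d))
            return (0.0, 1.0) if m == 0.0 else (float(np.sign(m) * np.inf), 0.0)
        t, p = spstats.ttest_1samp(d, 0.0)
        return float(t), float(p)

    rows = []
    for a, b in combinations(names, 2):
        t, p = _paired_t(series[a] - series[b])
        rows.append({
            "contrast": f"{a} vs {b}",
            "mean_diff": float(np.mean(series[a] - series[b])),
            "t": t, "p_raw": p,
        })
    if baseline == "chance":
        for name in names:
            t, p = _paired_t(series[name] - 0.5)
            rows.append({
                "contrast": f"{name} vs chance",
                "mean_diff": float(np.mean(series[name]) - 0.5),
                "t": t, "p_raw": p,
            })
    elif baseline in reports:
        pass  # already covered by the pairwise block
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["p_raw"], alpha=alpha, method="holm")
    out["p_holm"] = p_adj
    out["significant"] = reject
    return out
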