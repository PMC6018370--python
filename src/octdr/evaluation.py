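"""Cross-validation drivers, diagnostic metrics and bootstrap intervals.

Validation schemes follow clinical-imaging practice: leave-one-subject-out
(LOSO) and stratified k-fold (k = 2 or 4 by convention here, any k >= 2
allowed), always splitting by *subject* so the two correlated eyes of one
subject never straddle a train/test boundary.  Metrics are reported at the
subject level by default (DR probability of a subject = max over its
eyes); sensitivity takes DR (stage 1) and mild/moderate (stage 2) as the
positive class, the screening convention.  Bootstrap confidence intervals
resample subjects, respecting intra-subject eye correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classifier import AutoencoderSpec, pretrain_autoencoders, train_stage

_DR_GRADES = ("subclinical", "mild_moderate")


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Subject -> fold assignment.

    ``assignments`` has columns (subject_id, fold); both eyes of a subject
    share its fold by construction.
    """

    scheme: str                      # "loso" or "kfold"
    k: int
    assignments: pd.DataFrame
    stratified: bool = False

    @property
    def n_folds(self) -> int:
        return int(self.assignments["fold"].nunique())

    def test_subjects(self, fold: int) -> list[str]:
        a = self.assignments
        return sorted(a.loc[a["fold"] == fold, "subject_id"].unique())

    def train_subjects(self, fold: int) -> list[str]:
        a = self.assignments
        return sorted(a.loc[a["fold"] != fold, "subject_id"].unique())


def plan_folds(manifest: pd.DataFrame, scheme: str = "loso",
               k: int | None = None, seed: int = 0) -> FoldPlan:
    """Build a fold plan from a manifest with grade labels.

    LOSO gives one fold per subject.  k-fold is stratified by grade with a
    seeded shuffle inside each grade, then round-robin dealing, so the
    grade mix of every fold matches the cohort (e.g. an 80-subject
    40/20/20 cohort at k=2 yields two folds of 20 normal + 10 subclinical
    + 10 mild/moderate subjects each).
    """
    if "grade" not in manifest.columns or manifest["grade"].isna().any():
        raise ValueError("manifest must carry grade labels for fold planning")
    subjects = (manifest[["subject_id", "grade"]].drop_duplicates("subject_id")
                .sort_values("subject_id").reset_index(drop=True))
    n = len(subjects)
    if scheme == "loso":
        assignments = pd.DataFrame({
            "subject_id": subjects["subject_id"],
            "fold": np.arange(n),
        })
        return FoldPlan(scheme="loso", k=n, assignments=assignments)
    if scheme != "kfold":
        raise ValueError("scheme must be 'loso' or 'kfold'")
    if k is None or k < 2:
        raise ValueError("kfold requires k >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects ({n})")
    rng = np.random.default_rng(seed)
    rows = []
    for grade in sorted(subjects["grade"].unique()):
        ids = subjects.loc[subjects["grade"] == grade, "subject_id"].tolist()
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for i, sid in enumerate(ids):
            rows.append({"subject_id": sid, "fold": i % k})
    assignments = pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
    return FoldPlan(scheme="kfold", k=k, assignments=assignments, stratified=True)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by the rank (Mann–Whitney) formulation.

    Ties receive half credit.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks -> half credit for ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_ci(metric_fn, predictions: list, n_boot: int = 2000,
                 seed: int = 0, ci: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI of ``metric_fn`` over prediction records.

    Records are resampled as whole units — pass one record per *subject*
    so the resampling respects intra-subject eye correlation.
    """
    if len(predictions) < 2:
        raise ValueError("need at least 2 prediction records")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be unstable",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(predictions)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        stats[i] = metric_fn([predictions[j] for j in idx])
    alpha = (1 - ci) / 2
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, int]:
    """2x2 counts with the positive class encoded as 1."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return {
        "tp": int((y_true & y_pred).sum()),
        "tn": int((~y_true & ~y_pred).sum()),
        "fp": int((~y_true & y_pred).sum()),
        "fn": int((y_true & ~y_pred).sum()),
    }


@dataclass
class EvalReport:
    """Diagnostic metrics for one stage of one cross-validation run."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    ci95: tuple[float, float]
    confusion: dict[str, int]
    per_fold: list[float] = field(default_factory=list)
    n_train_runs: int = 0
    records: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.confusion
        total = c["tp"] + c["tn"] + c["fp"] + c["fn"]
        if total and abs(self.accuracy - (c["tp"] + c["tn"]) / total) > 1e-9:
            raise ValueError("accuracy inconsistent with the confusion counts")

    @classmethod
    def from_predictions(cls, y_true, y_pred, scores, per_fold=None,
                         n_train_runs=0, records=None, boot_seed=0,
                         n_boot=2000) -> "EvalReport":
        c = _confusion(y_true, y_pred)
        total = sum(c.values())
        acc = (c["tp"] + c["tn"]) / total
        sens = c["tp"] / (c["tp"] + c["fn"]) if c["tp"] + c["fn"] else float("nan")
        spec = c["tn"] / (c["tn"] + c["fp"]) if c["tn"] + c["fp"] else float("nan")
        auc = roc_auc(scores, y_true)
        correct = (np.asarray(y_true).astype(bool)
                   == np.asarray(y_pred).astype(bool)).astype(float)
        ci = bootstrap_ci(lambda recs: float(np.mean(recs)), list(correct),
                          n_boot=n_boot, seed=boot_seed)
        return cls(accuracy=acc, sensitivity=sens, specificity=spec, auc=auc,
                   ci95=ci, confusion=c, per_fold=per_fold or [],
                   n_train_runs=n_train_runs, records=records)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "ci95": list(self.ci95),
            "confusion": self.confusion,
            "per_fold": self.per_fold,
            "n_train_runs": self.n_train_runs,
        }


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

def run_cv(descriptors: list, plan: FoldPlan, spec: AutoencoderSpec,
           threshold: float = 0.5, aggregate: str = "subject",
           boot_seed: int = 0, n_boot: int = 2000,
           stages: tuple[str, ...] = ("screen", "grade"),
           ) -> dict[str, EvalReport]:
    """Cross-validated two-stage evaluation.

    Per fold: pretrain the 36 encoder stacks on the training eyes
    (unsupervised), train the screening head on all training eyes and the
    grading head on the DR training eyes, then score the held-out
    subjects.  CDF grids and all hyperparameters are fixed a priori;
    nothing is estimated on a test fold, and a guard raises if a test
    subject id ever appears in the training set.

    Stage-2 metrics are computed over subjects whose true label is DR.
    """
    if aggregate not in ("subject", "eye"):
        raise ValueError("aggregate must be 'subject' or 'eye'")
    by_subject: dict[str, list] = {}
    for d in descriptors:
        if d.grade_label is None:
            raise ValueError(f"descriptor {d.subject_id}/{d.eye} has no grade label")
        by_subject.setdefault(d.subject_id, []).append(d)
    plan_ids = set(plan.assignments["subject_id"])
    missing = set(by_subject) - plan_ids
    if missing:
        raise ValueError(f"plan does not cover subjects {sorted(missing)[:5]}")

    rows = []
    fold_ids = sorted(plan.assignments["fold"].unique())
    for fold in fold_ids:
        test_ids = [s for s in plan.test_subjects(fold) if s in by_subject]
        train_ids = [s for s in plan.train_subjects(fold) if s in by_subject]
        overlap = set(test_ids) & set(train_ids)
        if overlap:
            raise RuntimeError(
                f"leakage guard: subjects {sorted(overlap)[:5]} appear in both "
                f"training and test sets of fold {fold}")
        if not test_ids:
            continue
        train = [d for s in train_ids for d in by_subject[s]]
        train_labels = [d.grade_label for d in train]

        encoders = pretrain_autoencoders(train, spec)
        screen = grade = None
        if "screen" in stages:
            screen = train_stage(train, train_labels, "screen", spec,
                                 encoders=encoders)
        if "grade" in stages:
            dr_train = [d for d in train if d.grade_label in _DR_GRADES]
            grade = train_stage(dr_train, [d.grade_label for d in dr_train],
                                "grade", spec, encoders=encoders)

        for sid in test_ids:
            eyes = by_subject[sid]
            p_dr = (screen.predict_proba(eyes)[:, 1] if screen is not None
                    else np.full(len(eyes), np.nan))
            p_mm = (grade.predict_proba(eyes)[:, 1] if grade is not None
                    else np.full(len(eyes), np.nan))
            truth = eyes[0].grade_label
            if aggregate == "subject":
                rows.append({
                    "subject_id": sid, "fold": fold, "grade": truth,
                    "p_dr": float(p_dr.max()), "p_mm": float(p_mm.max()),
                })
            else:
                for d, p1, p2 in zip(eyes, p_dr, p_mm):
                    rows.append({"subject_id": sid, "eye": d.eye, "fold": fold,
                                 "grade": d.grade_label,
                                 "p_dr": float(p1), "p_mm": float(p2)})

    records = pd.DataFrame(rows)
    records["true_dr"] = records["grade"].isin(_DR_GRADES)
    records["pred_dr"] = records["p_dr"] >= threshold
    n_runs = len(fold_ids)

    out: dict[str, EvalReport] = {}
    if "screen" in stages:
        per_fold_1 = [
            float((g["true_dr"] == g["pred_dr"]).mean())
            for _, g in records.groupby("fold")
        ]
        out["screen"] = EvalReport.from_predictions(
            records["true_dr"].to_numpy(), records["pred_dr"].to_numpy(),
            records["p_dr"].to_numpy(), per_fold=per_fold_1,
            n_train_runs=n_runs, records=records, boot_seed=boot_seed,
            n_boot=n_boot)
    if "grade" not in stages:
        return out

    dr = records[records["true_dr"]].copy()
    dr["true_mm"] = dr["grade"] == "mild_moderate"
    dr["pred_mm"] = dr["p_mm"] >= 0.5
    per_fold_2 = [
        float((g["true_mm"] == g["pred_mm"]).mean())
        for _, g in dr.groupby("fold")
    ]
    out["grade"] = EvalReport.from_predictions(
        dr["true_mm"].to_numpy(), dr["pred_mm"].to_numpy(),
        dr["p_mm"].to_numpy(), per_fold=per_fold_2,
        n_train_runs=n_runs, records=dr, boot_seed=boot_seed, n_boot=n_boot)
    return out


def permutation_null(descriptors: list, spec: AutoencoderSpec,
                     n_permutations: int = 20, seed: int = 0) -> list[float]:
    """Stage-1 LOSO accuracies under subject-level label permutation.

    Grade labels are shuffled across subjects (both eyes of a subject keep
    the same permuted label), destroying any descriptor–label association;
    the cross-validated accuracy should then sit at chance level.  Returns
    one accuracy per permutation.
    """
    from dataclasses import replace

    subjects = sorted({d.subject_id for d in descriptors})
    grade_of = {}
    for d in descriptors:
        grade_of[d.subject_id] = d.grade_label
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_permutations):
        perm = rng.permutation(len(subjects))
        new_grade = {s: grade_of[subjects[j]] for s, j in zip(subjects, perm)}
        permuted = [replace(d, grade_label=new_grade[d.subject_id])
                    for d in descriptors]
        manifest = pd.DataFrame(
            [{"subject_id": d.subject_id, "eye": d.eye,
              "grade": d.grade_label} for d in permuted])
        plan = plan_folds(manifest, "loso")
        rep = run_cv(permuted, plan, spec, stages=("screen",), n_boot=100)
        accs.append(rep["screen"].accuracy)
    return accs
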