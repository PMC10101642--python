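"""Survival evaluation of risk stratification.

Kaplan–Meier estimation and the two-group log-rank test are implemented
natively (they carry the headline statistics and are checked against
brute-force risk-set oracles); Cox proportional-hazards models delegate to
lifelines with Breslow tie handling.  All KM / log-rank / area computations
truncate follow-up at the 10-year horizon (120 months) by default.

The pooled cross-validation driver fits a classifier per fold (optionally
with a second cohort always in the training side), predicts each held-out
patient exactly once, and evaluates the pooled predictions: log-rank
between predicted groups, the ordered area-between-curves (ABC) triple
against the true risk groups, confusion metrics with HIGH as the positive
class, and hazard ratios.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold

from .cohorts import HORIZON_MONTHS


@dataclass
class SurvivalData:
    """Times in months with 1 = event, 0 = censored."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must align")
        if (self.time < 0).any():
            raise ValueError("negative survival times")

    def __len__(self):
        return len(self.time)

    def truncated(self, horizon: float) -> "SurvivalData":
        """Censor any follow-up beyond the horizon at the horizon."""
        time = np.minimum(self.time, horizon)
        event = np.where(self.time > horizon, 0, self.event)
        return SurvivalData(time, event)


@dataclass
class KMCurve:
    event_times: np.ndarray   # ascending distinct event times
    survival: np.ndarray      # S(t) just after each event time
    at_risk: np.ndarray
    horizon: float

    def at(self, t: float) -> float:
        """S(t) (right-continuous step function; S(0) = 1)."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_labels(cls, true, predicted) -> "ConfusionCounts":
        true = np.asarray(true)
        predicted = np.asarray(predicted)
        return cls(
            tp=int(((true == 1) & (predicted == 1)).sum()),
            fp=int(((true == 0) & (predicted == 1)).sum()),
            tn=int(((true == 0) & (predicted == 0)).sum()),
            fn=int(((true == 1) & (predicted == 0)).sum()),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class CVPlan:
    k: int
    fold_of: np.ndarray  # fold index per patient
    seed: int

    def __post_init__(self):
        self.fold_of = np.asarray(self.fold_of, dtype=int)
        present = np.unique(self.fold_of)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError("folds must partition patients into 0..k-1")


@dataclass
class StratificationReport:
    predictions: pd.DataFrame
    logrank_chi2: float
    logrank_p: float
    abc: tuple | None
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    hazard_ratio: dict | None
    per_fold: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "abc": list(self.abc) if self.abc is not None else None,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "hazard_ratio": self.hazard_ratio,
            "per_fold": self.per_fold,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# estimators and tests
# ---------------------------------------------------------------------------


def km_estimate(data: SurvivalData, horizon: float = HORIZON_MONTHS) -> KMCurve:
    """Product-limit estimator S(t) = ∏_{t_i ≤ t} (1 − d_i / n_i)."""
    if len(data) < 1:
        raise ValueError("need at least one subject")
    d = data.truncated(horizon)
    order = np.argsort(d.time, kind="stable")
    time, event = d.time[order], d.event[order]
    ev_times = np.unique(time[event == 1])
    surv, risk = [], []
    s = 1.0
    for t in ev_times:
        n_i = int((time >= t).sum())
        d_i = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        risk.append(n_i)
    return KMCurve(ev_times, np.array(surv), np.array(risk, dtype=int), horizon)


def km_auc(curve: KMCurve, horizon: float = HORIZON_MONTHS) -> float:
    """Exact step-function integral of S(t) over [0, horizon] (months)."""
    ts = np.concatenate([[0.0], curve.event_times[curve.event_times <= horizon], [horizon]])
    area = 0.0
    s = 1.0
    for left, right in zip(ts[:-1], ts[1:]):
        area += s * (right - left)
        s = curve.at(right)
    return float(area)


def logrank_test(a: SurvivalData, b: SurvivalData,
                 horizon: float = HORIZON_MONTHS) -> tuple[float, float]:
    """Two-group log-rank test truncated at the horizon.

    At each distinct event time the observed events in group ``a`` are
    compared with their hypergeometric expectation given the pooled risk
    set; χ² = (ΣO − ΣE)² / ΣV with 1 df.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    at, bt = a.truncated(horizon), b.truncated(horizon)
    times = np.concatenate([at.time, bt.time])
    events = np.concatenate([at.event, bt.event])
    group = np.concatenate([np.zeros(len(at)), np.ones(len(bt))])
    ev_times = np.unique(times[events == 1])
    if ev_times.size == 0:
        warnings.warn("no events in either group; log-rank undefined, p = 1")
        return 0.0, 1.0
    O = E = V = 0.0
    for t in ev_times:
        at_risk = times >= t
        n_j = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        dying = (times == t) & (events == 1)
        d_j = dying.sum()
        d1 = (dying & (group == 0)).sum()
        O += d1
        E += d_j * n1 / n_j
        if n_j > 1:
            V += d_j * (n1 / n_j) * (1 - n1 / n_j) * (n_j - d_j) / (n_j - 1)
    if V == 0:
        warnings.warn("zero log-rank variance; p = 1")
        return 0.0, 1.0
    chi2 = (O - E) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def abc_metric(true_low: SurvivalData, pred_low: SurvivalData,
               pred_high: SurvivalData, true_high: SurvivalData,
               horizon: float = HORIZON_MONTHS) -> tuple[float, float, float]:
    """Ordered area-between-curves triple (months), top to bottom:
    true-low − predicted-low, predicted-low − predicted-high,
    predicted-high − true-high."""
    groups = (true_low, pred_low, pred_high, true_high)
    if any(len(g) == 0 for g in groups):
        raise ValueError("all four groups must be non-empty")
    aucs = [km_auc(km_estimate(g, horizon), horizon) for g in groups]
    return (aucs[0] - aucs[1], aucs[1] - aucs[2], aucs[2] - aucs[3])


def confusion_metrics(counts: ConfusionCounts):
    """(accuracy, sensitivity, specificity); undefined ratios are None."""
    if counts.n == 0:
        raise ValueError("no predictions")
    accuracy = (counts.tp + counts.tn) / counts.n
    p = counts.tp + counts.fn
    n = counts.tn + counts.fp
    sensitivity = counts.tp / p if p else None
    specificity = counts.tn / n if n else None
    if sensitivity is None:
        warnings.warn("no positive subjects; sensitivity undefined")
    if specificity is None:
        warnings.warn("no negative subjects; specificity undefined")
    return accuracy, sensitivity, specificity


def cox_hazard_ratio(df: pd.DataFrame, covariates,
                     time_col: str = "time", event_col: str = "event") -> dict:
    """Cox proportional-hazards fit (lifelines, Breslow ties).

    ``covariates``: column names to include (one for univariate).  Returns
    per-covariate hazard ratios with Wald 95% CIs and p-values, plus a
    ``converged`` flag (non-convergence or separation is flagged, not
    silent).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    covariates = list(covariates)
    sub = df[[time_col, event_col] + covariates].copy()
    fitter = CoxPHFitter()
    result = {"converged": True, "covariates": {}}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(sub, duration_col=time_col, event_col=event_col)
    except ConvergenceError as exc:
        return {"converged": False, "error": str(exc), "covariates": {}}
    summary = fitter.summary
    for cov in summary.index:
        row = summary.loc[cov]
        # near-separation fits can push a CI bound past float range; an
        # infinite bound is a legitimate (flagged-by-inspection) result
        with np.errstate(over="ignore"):
            result["covariates"][str(cov)] = {
                "hr": float(np.exp(row["coef"])),
                "ci_low": float(np.exp(row["coef lower 95%"])),
                "ci_high": float(np.exp(row["coef upper 95%"])),
                "p": float(row["p"]),
            }
    return result


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def make_cv_plan(y, k: int = 5, seed: int = 0, stratified: bool = True) -> CVPlan:
    """k-fold assignment, stratified by risk class by default."""
    y = np.asarray(y)
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        fold_of[test_idx] = fold
    return CVPlan(k, fold_of, seed)


def evaluate_predictions(df: pd.DataFrame,
                         horizon: float = HORIZON_MONTHS,
                         per_fold: list | None = None) -> StratificationReport:
    """Build a StratificationReport from pooled predictions.

    ``df`` columns: patient_id, fold, score, predicted, true_label, time,
    event.
    """
    pred_low = SurvivalData(df.loc[df.predicted == 0, "time"],
                            df.loc[df.predicted == 0, "event"]) \
        if (df.predicted == 0).any() else None
    pred_high = SurvivalData(df.loc[df.predicted == 1, "time"],
                             df.loc[df.predicted == 1, "event"]) \
        if (df.predicted == 1).any() else None
    if pred_low is None or pred_high is None:
        warnings.warn("one predicted group is empty; log-rank/ABC undefined")
        chi2, p, abc = float("nan"), 1.0, None
    else:
        chi2, p = logrank_test(pred_low, pred_high, horizon)
        true_low = SurvivalData(df.loc[df.true_label == 0, "time"],
                                df.loc[df.true_label == 0, "event"])
        true_high = SurvivalData(df.loc[df.true_label == 1, "time"],
                                 df.loc[df.true_label == 1, "event"])
        abc = abc_metric(true_low, pred_low, pred_high, true_high, horizon)
    counts = ConfusionCounts.from_labels(df.true_label, df.predicted)
    accuracy, sensitivity, specificity = confusion_metrics(counts)
    cox_df = df.rename(columns={"predicted": "predicted_high"})
    hr = cox_hazard_ratio(cox_df, ["predicted_high"]) \
        if df.event.sum() > 0 and df.predicted.nunique() > 1 else None
    return StratificationReport(df, chi2, p, abc, accuracy, sensitivity,
                                specificity, hr, per_fold or [])


def crossval_pool(X, y, survival: SurvivalData, plan: CVPlan, estimator,
                  patient_ids=None, extra_train=None,
                  horizon: float = HORIZON_MONTHS) -> StratificationReport:
    """Pooled k-fold cross-validation of an image classifier.

    For each fold, a clone of ``estimator`` is fitted on the other k−1
    folds — plus, when given, ``extra_train = (X_extra, y_extra)``, a
    second cohort that joins every training set — and predicts the held-out
    fold.  Every target patient appears exactly once in the pooled
    predictions, which are then evaluated jointly.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if patient_ids is None:
        patient_ids = [str(i) for i in range(len(X))]
    if len(plan.fold_of) != len(X):
        raise ValueError("plan does not cover the target cohort")
    if extra_train is not None:
        Xe = np.asarray(extra_train[0], dtype=np.float32)
        ye = np.asarray(extra_train[1], dtype=np.int64)
        if Xe.shape[1:] != X.shape[1:]:
            raise ValueError("extra_train images have a different shape")
        extra_ids = set() if len(extra_train) < 3 else set(extra_train[2])
        overlap = extra_ids & set(patient_ids)
        if overlap:
            raise ValueError(f"extra_train overlaps target cohort: {sorted(overlap)[:5]}")
    rows = []
    per_fold = []
    for fold in range(plan.k):
        test = plan.fold_of == fold
        train = ~test
        X_tr, y_tr = X[train], y[train]
        if extra_train is not None:
            X_tr = np.concatenate([X_tr, Xe])
            y_tr = np.concatenate([y_tr, ye])
        model = clone(estimator)
        if "random_state" in model.get_params():
            # per-fold seed derived from the plan seed, below 2**31
            model.set_params(random_state=(plan.seed * 31 + fold) % (2**31 - 1))
        model.fit(X_tr, y_tr)
        scores = model.predict_proba(X[test])[:, 1]
        for i, score in zip(np.flatnonzero(test), scores):
            rows.append({
                "patient_id": patient_ids[i], "fold": fold,
                "score": float(score), "predicted": int(score >= 0.5),
                "true_label": int(y[i]),
                "time": float(survival.time[i]), "event": int(survival.event[i]),
            })
        fold_df = pd.DataFrame(rows[-int(test.sum()):])
        fold_acc = float((fold_df.predicted == fold_df.true_label).mean())
        fold_stats = {"fold": fold, "n_test": int(test.sum()), "accuracy": fold_acc}
        if fold_df.predicted.nunique() > 1:
            c2, pp = logrank_test(
                SurvivalData(fold_df.loc[fold_df.predicted == 0, "time"],
                             fold_df.loc[fold_df.predicted == 0, "event"]),
                SurvivalData(fold_df.loc[fold_df.predicted == 1, "time"],
                             fold_df.loc[fold_df.predicted == 1, "event"]),
                horizon)
            fold_stats.update(logrank_chi2=c2, logrank_p=pp)
        per_fold.append(fold_stats)
    df = pd.DataFrame(rows)
    if sorted(df.patient_id) != sorted(patient_ids):
        raise AssertionError("pooled predictions do not cover each patient once")
    return evaluate_predictions(df, horizon, per_fold)
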