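"""Cohort assembly: expression matrices, cross-platform rescaling, merging
and 10-year composite risk labelling.

Expression values arrive platform-normalised (e.g. median Z-scores from a
microarray cohort next to RNA-seq estimates) and are made comparable by a
gene-wise affine rescaling that sends each gene's 2.5th percentile to −1 and
its 97.5th percentile to +1.  Cohorts are then merged on their shared genes,
genes with expression missing in more than a handful of patients are
dropped, and patients with any remaining missing value are excluded.

Risk labels implement a 10-year composite endpoint: a patient is HIGH risk
if disease-specific death, locoregional or distant recurrence, or
progression is recorded strictly before the horizon (default 120 months);
LOW risk if event-free with at least the horizon of follow-up; otherwise
the patient is ineligible (insufficient follow-up).  Normal-like intrinsic
subtype samples are excluded up front.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HORIZON_MONTHS = 120.0
DAYS_PER_MONTH = 30.44

#: qualifying-event attribute names on ClinicalRecord, by endpoint set
EVENT_SETS = {
    # microarray discovery cohort convention
    "mb": ("dss", "locoregional", "distant"),
    # RNA-seq validation cohort convention
    "tcga": ("dss", "progression", "locoregional", "distant"),
    # default: union of both
    "union": ("dss", "locoregional", "distant", "progression"),
}


class RiskLabel(enum.Enum):
    LOW = 0
    HIGH = 1
    INELIGIBLE = 2


@dataclass
class RescaleParams:
    """Percentile anchors of the cross-platform affine rescaling."""

    p_lo: float = 2.5
    p_hi: float = 97.5
    lo_target: float = -1.0
    hi_target: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.p_lo < self.p_hi <= 100.0):
            raise ValueError("need 0 <= p_lo < p_hi <= 100")
        if self.lo_target >= self.hi_target:
            raise ValueError("lo_target must be below hi_target")


@dataclass
class ExpressionMatrix:
    """Genes × patients expression grid; NaN marks a missing cell."""

    gene_ids: list[str]
    patient_ids: list[str]
    values: np.ndarray
    cohort_tag: str = ""
    cohort_of: dict[str, str] | None = None  # per-patient tag after merging

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids")
        if self.values.shape != (len(self.gene_ids), len(self.patient_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.patient_ids)})"
            )
        if self.cohort_of is None:
            self.cohort_of = {p: self.cohort_tag for p in self.patient_ids}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.patient_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cohort_tag: str = "") -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), cohort_tag)

    @classmethod
    def read_csv(cls, path, cohort_tag: str = "", sep=None) -> "ExpressionMatrix":
        """Read a genes-in-rows table (first column = gene symbol).

        Tab- or comma-separated is auto-detected when ``sep`` is None.
        Empty cells are missing values.
        """
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        df.index = df.index.astype(str)
        return cls.from_frame(df, cohort_tag)

    def write_csv(self, path, sep=","):
        self.to_frame().to_csv(path, sep=sep, index_label="gene")


@dataclass
class ClinicalRecord:
    """One patient's follow-up; event times in months from diagnosis."""

    patient_id: str
    follow_up_months: float
    dss_event: int = 0
    dss_time: float | None = None
    t_locoregional: float | None = None
    t_distant: float | None = None
    t_progression: float | None = None
    subtype: str = ""
    stage: int | None = None
    er: int | None = None
    pr: int | None = None
    her2: int | None = None

    def event_time(self, kind: str) -> float | None:
        if kind == "dss":
            return self.dss_time if self.dss_event else None
        return {"locoregional": self.t_locoregional,
                "distant": self.t_distant,
                "progression": self.t_progression}[kind]


@dataclass
class RiskLabeledCohort:
    """Merged, rescaled expression plus labels and survival records."""

    expression: ExpressionMatrix
    labels: dict[str, RiskLabel]
    survival: dict[str, tuple[float, int]]  # (time months, event flag)
    cohort_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        pats = set(self.expression.patient_ids)
        for name, mapping in (("labels", self.labels), ("survival", self.survival)):
            if set(mapping) != pats:
                raise ValueError(f"{name} keys do not match expression patients")
        if any(v is RiskLabel.INELIGIBLE for v in self.labels.values()):
            raise ValueError("cohort contains INELIGIBLE patients")
        if np.isnan(self.expression.values).any():
            raise ValueError("cohort expression contains missing values")
        if not self.cohort_of:
            self.cohort_of = dict(self.expression.cohort_of)

    @property
    def patient_ids(self) -> list[str]:
        return self.expression.patient_ids

    def label_array(self) -> np.ndarray:
        """0 = LOW, 1 = HIGH, ordered like the expression patient axis."""
        return np.array(
            [self.labels[p].value for p in self.expression.patient_ids], dtype=np.int64
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def rescale_percentile(matrix: ExpressionMatrix,
                       params: RescaleParams | None = None) -> ExpressionMatrix:
    """Gene-wise affine rescaling onto the percentile anchors.

    Per gene, the map sending the gene's ``p_lo``-th percentile to
    ``lo_target`` and ``p_hi``-th to ``hi_target`` (linear-interpolation
    quantiles over non-missing values) is applied to every non-missing
    cell.  Values outside the window land beyond the targets — no clipping
    here; the bounded range is only enforced at image conversion.
    """
    params = params or RescaleParams()
    values = matrix.values
    lo = np.nanpercentile(values, params.p_lo, axis=1)
    hi = np.nanpercentile(values, params.p_hi, axis=1)
    spread = hi - lo
    bad = ~(spread > 0)
    if bad.any():
        names = [g for g, b in zip(matrix.gene_ids, bad) if b]
        raise ValueError(
            "constant gene row(s) — zero percentile spread: " + ", ".join(names[:10])
        )
    scale = (params.hi_target - params.lo_target) / spread
    out = (values - lo[:, None]) * scale[:, None] + params.lo_target
    return replace(matrix, values=out)


def merge_cohorts(a: ExpressionMatrix, b: ExpressionMatrix,
                  max_missing_patients: int = 5) -> ExpressionMatrix:
    """Merge two rescaled cohorts on shared genes.

    Keeps genes present in both cohorts whose value is missing in at most
    ``max_missing_patients`` patients across the concatenated patient axis.
    """
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise ValueError("cohorts share no genes")
    dup = set(a.patient_ids) & set(b.patient_ids)
    if dup:
        raise ValueError(f"duplicate patient ids across cohorts: {sorted(dup)[:5]}")
    ia = {g: i for i, g in enumerate(a.gene_ids)}
    ib = {g: i for i, g in enumerate(b.gene_ids)}
    rows_a = np.array([ia[g] for g in shared])
    rows_b = np.array([ib[g] for g in shared])
    values = np.concatenate([a.values[rows_a], b.values[rows_b]], axis=1)
    keep = np.isnan(values).sum(axis=1) <= max_missing_patients
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("merge_cohorts: dropping %d genes exceeding missingness cap", n_drop)
    genes = [g for g, k in zip(shared, keep) if k]
    cohort_of = {p: a.cohort_of[p] for p in a.patient_ids}
    cohort_of.update({p: b.cohort_of[p] for p in b.patient_ids})
    tag = f"{a.cohort_tag}+{b.cohort_tag}"
    return ExpressionMatrix(genes, a.patient_ids + b.patient_ids, values[keep],
                            tag, cohort_of)


def drop_incomplete_patients(matrix: ExpressionMatrix,
                             return_removed: bool = False):
    """Remove patients with any missing value in the retained gene set."""
    complete = ~np.isnan(matrix.values).any(axis=0)
    removed = [p for p, ok in zip(matrix.patient_ids, complete) if not ok]
    if removed:
        logger.info("drop_incomplete_patients: removed %d patients: %s",
                    len(removed), removed)
    if not complete.any():
        logger.warning("drop_incomplete_patients: no complete patients remain")
    kept = [p for p, ok in zip(matrix.patient_ids, complete) if ok]
    out = ExpressionMatrix(
        list(matrix.gene_ids), kept, matrix.values[:, complete],
        matrix.cohort_tag, {p: matrix.cohort_of[p] for p in kept},
    )
    return (out, removed) if return_removed else out


def assign_risk(record: ClinicalRecord,
                horizon_months: float = HORIZON_MONTHS,
                event_set: str | tuple[str, ...] = "union") -> RiskLabel:
    """10-year composite risk label.

    HIGH if any qualifying event occurred strictly before the horizon; LOW
    if no qualifying event and follow-up reaches the horizon; otherwise
    INELIGIBLE (event-free but insufficient follow-up).  An event at
    exactly the horizon is *not* before 10 years, hence not HIGH.
    """
    kinds = EVENT_SETS[event_set] if isinstance(event_set, str) else tuple(event_set)
    times = []
    for kind in kinds:
        t = record.event_time(kind)
        if t is not None:
            if t < 0:
                raise ValueError(f"negative event time for {record.patient_id}")
            times.append(t)
    if record.follow_up_months < 0:
        raise ValueError(f"negative follow-up for {record.patient_id}")
    if any(t < horizon_months for t in times):
        return RiskLabel.HIGH
    if record.follow_up_months >= horizon_months:
        return RiskLabel.LOW
    return RiskLabel.INELIGIBLE


def filter_inclusion(records: list[ClinicalRecord],
                     horizon_months: float = HORIZON_MONTHS,
                     event_set: str | tuple[str, ...] = "union",
                     exclude_subtypes: tuple[str, ...] = ("normal-like",)):
    """Apply the inclusion criteria and label survivors.

    Returns ``(eligible_records, labels, summary)`` where ``summary`` counts
    HIGH/LOW patients and exclusions by rule.
    """
    eligible, labels = [], {}
    summary = {"n_high": 0, "n_low": 0,
               "excluded_subtype": 0, "excluded_followup": 0}
    for rec in records:
        if rec.subtype.strip().lower() in exclude_subtypes:
            summary["excluded_subtype"] += 1
            continue
        label = assign_risk(rec, horizon_months, event_set)
        if label is RiskLabel.INELIGIBLE:
            summary["excluded_followup"] += 1
            continue
        eligible.append(rec)
        labels[rec.patient_id] = label
        summary["n_high" if label is RiskLabel.HIGH else "n_low"] += 1
    logger.info("filter_inclusion: %s", summary)
    return eligible, labels, summary


def survival_from_record(record: ClinicalRecord,
                         event_set: str | tuple[str, ...] = "union") -> tuple[float, int]:
    """(time, event) pair for survival analysis: time to first qualifying
    event, else censoring at last follow-up."""
    kinds = EVENT_SETS[event_set] if isinstance(event_set, str) else tuple(event_set)
    times = [t for kind in kinds if (t := record.event_time(kind)) is not None]
    if times:
        return (min(times), 1)
    return (record.follow_up_months, 0)


def read_clinical_csv(path) -> list[ClinicalRecord]:
    """Read the clinical table (blank cells = unavailable)."""
    df = pd.read_csv(path)
    records = []
    opt = lambda v: None if pd.isna(v) else float(v)
    for _, row in df.iterrows():
        records.append(ClinicalRecord(
            patient_id=str(row["patient_id"]),
            follow_up_months=float(row["follow_up_months"]),
            dss_event=int(row.get("dss_event", 0) or 0),
            dss_time=opt(row.get("dss_time")),
            t_locoregional=opt(row.get("t_locoregional")),
            t_distant=opt(row.get("t_distant")),
            t_progression=opt(row.get("t_progression")),
            subtype=str(row.get("subtype", "") or ""),
            stage=None if pd.isna(row.get("stage")) else int(row.get("stage")),
            er=None if pd.isna(row.get("er")) else int(row.get("er")),
            pr=None if pd.isna(row.get("pr")) else int(row.get("pr")),
            her2=None if pd.isna(row.get("her2")) else int(row.get("her2")),
        ))
    return records


def build_cohort(expression: ExpressionMatrix,
                 records: list[ClinicalRecord],
                 horizon_months: float = HORIZON_MONTHS,
                 event_set: str | tuple[str, ...] = "union") -> RiskLabeledCohort:
    """Assemble a RiskLabeledCohort from rescaled expression + clinical data.

    Patients must be eligible and present in both inputs; patients missing
    from either side are dropped (logged).
    """
    eligible, labels, _ = filter_inclusion(records, horizon_months, event_set)
    by_id = {r.patient_id: r for r in eligible}
    keep = [p for p in expression.patient_ids if p in by_id]
    dropped = [p for p in expression.patient_ids if p not in by_id]
    if dropped:
        logger.info("build_cohort: dropping %d patients without eligible clinical "
                    "records", len(dropped))
    idx = [expression.patient_ids.index(p) for p in keep]
    expr = ExpressionMatrix(list(expression.gene_ids), keep,
                            expression.values[:, idx], expression.cohort_tag,
                            {p: expression.cohort_of[p] for p in keep})
    survival = {p: survival_from_record(by_id[p], event_set) for p in keep}
    return RiskLabeledCohort(expr, {p: labels[p] for p in keep}, survival)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_cohort_h5(cohort: RiskLabeledCohort, path):
    pats = cohort.expression.patient_ids
    with h5py.File(path, "w") as f:
        f.create_dataset("expression", data=cohort.expression.values)
        f.create_dataset("gene_ids", data=np.array(cohort.expression.gene_ids, dtype="S"))
        f.create_dataset("patient_ids", data=np.array(pats, dtype="S"))
        f.create_dataset("labels", data=cohort.label_array())
        f.create_dataset("surv_time", data=np.array([cohort.survival[p][0] for p in pats]))
        f.create_dataset("surv_event", data=np.array([cohort.survival[p][1] for p in pats]))
        f.create_dataset("cohort_of", data=np.array([cohort.cohort_of[p] for p in pats], dtype="S"))
        f.attrs["cohort_tag"] = cohort.expression.cohort_tag


def load_cohort_h5(path) -> RiskLabeledCohort:
    with h5py.File(path, "r") as f:
        genes = [g.decode() for g in f["gene_ids"][()]]
        pats = [p.decode() for p in f["patient_ids"][()]]
        expr = ExpressionMatrix(genes, pats, f["expression"][()],
                                f.attrs.get("cohort_tag", ""))
        labels = {p: RiskLabel(int(v)) for p, v in zip(pats, f["labels"][()])}
        surv = {p: (float(t), int(e)) for p, t, e in
                zip(pats, f["surv_time"][()], f["surv_event"][()])}
        cohort_of = {p: c.decode() for p, c in zip(pats, f["cohort_of"][()])}
    expr.cohort_of = cohort_of
    return RiskLabeledCohort(expr, labels, surv, cohort_of)
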