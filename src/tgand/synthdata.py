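"""Synthetic two-cohort transcriptome generator with known risk labels.

The generative family is deliberately the simplest one whose labels are
recoverable both from expression and from survival: a Gaussian class-shift
model (a subset of informative genes carries a mean shift of ``delta``
between risk classes, all genes share within-class noise ``sigma``) paired
with exponential event times whose hazard depends on the class.  High-risk
patients receive a qualifying event strictly before the 10-year horizon by
sampling from the exponential *conditioned* on landing inside the window
(keeping the time distribution smooth rather than truncating); low-risk
patients are event-free with follow-up at or beyond the horizon, and a
fraction carry a late (post-horizon) event to exercise the strictness of
the labelling rule.  A second cohort is emulated by a per-gene affine
platform shift plus fresh measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohorts import (
    ClinicalRecord,
    ExpressionMatrix,
    RiskLabel,
    RiskLabeledCohort,
    assign_risk,
    rescale_percentile,
    survival_from_record,
)

_SUBTYPES = ("luminal-A", "luminal-B", "HER2-enriched", "basal-like")
_EVENT_KINDS = ("dss", "locoregional", "distant", "progression")


@dataclass
class SynthConfig:
    n: int = 300
    m: int = 512
    prevalence_high: float = 0.5
    n_informative: int = 64
    delta: float = 2.0           # between-class mean shift on informative genes
    sigma: float = 1.0           # within-class expression sd
    platform_scale: tuple[float, float] = (0.6, 1.6)
    platform_offset: tuple[float, float] = (-0.5, 0.5)
    platform_noise_sd: float = 0.1
    hazard_low: float = 0.005    # monthly event hazard, low-risk class
    hazard_high: float = 0.05
    censor_max_months: float = 240.0
    late_event_frac: float = 0.15
    horizon: float = 120.0
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.m:
            raise ValueError("n_informative cannot exceed m")
        if not (self.hazard_high > self.hazard_low > 0):
            raise ValueError("need hazard_high > hazard_low > 0")
        if not (0.0 < self.prevalence_high < 1.0):
            raise ValueError("prevalence_high must be in (0, 1)")
        if self.censor_max_months <= self.horizon:
            raise ValueError("censor_max_months must exceed the horizon")


@dataclass
class SynthCohort:
    expression: ExpressionMatrix
    clinical: list[ClinicalRecord]
    truth: dict[str, RiskLabel]
    informative_gene_ids: list[str]

    def truth_array(self) -> np.ndarray:
        return np.array([self.truth[p].value for p in self.expression.patient_ids],
                        dtype=np.int64)


def _conditional_exponential(rng, lam, upper, size):
    """Exponential(lam) samples conditioned on being < upper (inverse CDF)."""
    u = rng.uniform(0.0, 1.0, size=size)
    return -np.log1p(-u * (1.0 - np.exp(-lam * upper))) / lam


def simulate_cohort(config: SynthConfig, cohort_tag: str = "synthA") -> SynthCohort:
    """Draw one cohort; reproducible given ``config.seed``.

    Guarantees that :func:`~tgand.cohorts.assign_risk` applied to the
    generated clinical records reproduces the ground-truth labels exactly.
    """
    ss = np.random.SeedSequence(config.seed)
    r_class, r_expr, r_surv, r_meta = (np.random.default_rng(s) for s in ss.spawn(4))

    n, m = config.n, config.m
    patient_ids = [f"{cohort_tag}-P{i:05d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(m)]
    is_high = r_class.uniform(size=n) < config.prevalence_high

    informative = sorted(r_expr.choice(m, size=config.n_informative, replace=False))
    values = r_expr.normal(0.0, config.sigma, size=(m, n))
    shift = np.where(is_high, config.delta / 2.0, -config.delta / 2.0)
    values[informative, :] += shift[None, :]

    clinical: list[ClinicalRecord] = []
    truth: dict[str, RiskLabel] = {}
    h = config.horizon
    for i, pid in enumerate(patient_ids):
        subtype = _SUBTYPES[r_meta.integers(len(_SUBTYPES))]
        stage = int(r_meta.integers(1, 5))
        er, pr, her2 = (int(r_meta.integers(2)) for _ in range(3))
        kwargs = dict(subtype=subtype, stage=stage, er=er, pr=pr, her2=her2)
        if is_high[i]:
            t = float(_conditional_exponential(r_surv, config.hazard_high, h, None))
            kind = _EVENT_KINDS[r_surv.integers(len(_EVENT_KINDS))]
            follow = t
            rec = ClinicalRecord(pid, follow, **kwargs)
            if kind == "dss":
                rec.dss_event, rec.dss_time = 1, t
            else:
                setattr(rec, f"t_{kind}", t)
                # non-fatal event: follow-up continues past the event
                rec.follow_up_months = t + float(r_surv.exponential(1.0 / config.hazard_high))
            truth[pid] = RiskLabel.HIGH
        else:
            follow = float(r_surv.uniform(h, config.censor_max_months))
            rec = ClinicalRecord(pid, follow, **kwargs)
            if follow > h + 1.0 and r_surv.uniform() < config.late_event_frac:
                # post-horizon event must not flip the label
                rec.dss_event = 1
                rec.dss_time = float(r_surv.uniform(h + 1.0, follow))
            truth[pid] = RiskLabel.LOW
        clinical.append(rec)
        assert assign_risk(rec, h) is truth[pid], "generator/label inconsistency"

    expr = ExpressionMatrix(gene_ids, patient_ids, values, cohort_tag)
    return SynthCohort(expr, clinical, truth, [gene_ids[i] for i in informative])


def apply_platform_shift(cohort: SynthCohort, config: SynthConfig, seed: int,
                         cohort_tag: str = "synthB",
                         patient_suffix: str | None = None) -> SynthCohort:
    """Re-measure a cohort on an emulated second platform.

    Applies a per-gene affine transform (scale and offset drawn uniformly
    from the configured ranges) plus fresh measurement noise.  Gene ids and
    truth labels are unchanged; the cohort tag changes, and patient ids can
    be suffixed so the shifted cohort can be merged with the original.
    """
    rng = np.random.default_rng(seed)
    m = cohort.expression.n_genes
    scale = rng.uniform(*config.platform_scale, size=m)
    offset = rng.uniform(*config.platform_offset, size=m)
    values = cohort.expression.values * scale[:, None] + offset[:, None]
    if config.platform_noise_sd > 0:
        values = values + rng.normal(0.0, config.platform_noise_sd, size=values.shape)

    if patient_suffix:
        rename = {p: p + patient_suffix for p in cohort.expression.patient_ids}
    else:
        rename = {p: p for p in cohort.expression.patient_ids}
    patient_ids = [rename[p] for p in cohort.expression.patient_ids]
    expr = ExpressionMatrix(list(cohort.expression.gene_ids), patient_ids,
                            values, cohort_tag)
    clinical = [replace(rec, patient_id=rename[rec.patient_id])
                for rec in cohort.clinical]
    truth = {rename[p]: lab for p, lab in cohort.truth.items()}
    return SynthCohort(expr, clinical, truth, list(cohort.informative_gene_ids))


def to_risk_labeled(cohort: SynthCohort, rescale: bool = True,
                    event_set: str = "union") -> RiskLabeledCohort:
    """Rescale a synthetic cohort and package it for the pipeline."""
    expr = rescale_percentile(cohort.expression) if rescale else cohort.expression
    by_id = {r.patient_id: r for r in cohort.clinical}
    survival = {p: survival_from_record(by_id[p], event_set)
                for p in expr.patient_ids}
    return RiskLabeledCohort(expr, dict(cohort.truth), survival)
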