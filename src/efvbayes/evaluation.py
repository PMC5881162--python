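"""Classifier performance: confusion matrices, sensitivity/specificity,
ROC across candidate sampling times, and blinded-cohort verification.

Per phenotype, with N_i true subjects of phenotype i of whom d_i are called i,
and M_i subjects of other phenotypes of whom f_i are called i:

    sensitivity  P(+|+) = d_i / N_i
    specificity  P(−|−) = (M_i − f_i) / M_i
    false-positive probability P(+|−) = 1 − P(−|−)

Fractions are formed on integer counts (exact) before conversion to float.
The optimal sampling time for a target phenotype maximizes Youden's
J = P(+|+) − P(+|−) over the candidate times, ties broken toward the later
time (a later clinic visit is logistically simpler and the customary choice).
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import BinnedConditionalTable, PhenotypeCall, classify, fit_conditional_table
from .dataset import CohortDataset
from .phenotype import PHENOTYPES, Phenotype, coerce_phenotype


@dataclass(frozen=True)
class ConfusionMatrix:
    """3×3 counts, rows = true phenotype, columns = predicted phenotype."""

    counts: np.ndarray  # int, shape (3, 3), EM/IM/PM order

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("confusion matrix must be 3x3 with counts >= 0")

    def frame(self) -> pd.DataFrame:
        labels = [ph.value for ph in PHENOTYPES]
        return pd.DataFrame(self.counts, index=labels, columns=labels)

    def normalized(self) -> pd.DataFrame:
        """Row-normalized P(predicted | true); all-zero rows become NaN."""
        c = self.counts.astype(float)
        totals = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals > 0, c / totals, np.nan)
        labels = [ph.value for ph in PHENOTYPES]
        return pd.DataFrame(p, index=labels, columns=labels)

    def undefined_rows(self) -> list[Phenotype]:
        return [ph for i, ph in enumerate(PHENOTYPES) if self.counts[i].sum() == 0]


@dataclass(frozen=True)
class PhenotypePerformance:
    phenotype: Phenotype
    true_positive_prob: float | None  # P(+|+); None when no true subjects
    true_negative_prob: float | None  # P(−|−); None when no negatives
    false_positive_prob: float | None  # P(+|−) = 1 − P(−|−)
    n_true: int
    n_not_true: int


@dataclass(frozen=True)
class PerformanceSummary:
    per_phenotype: dict[Phenotype, PhenotypePerformance]

    def frame(self) -> pd.DataFrame:
        rows = []
        for ph in PHENOTYPES:
            p = self.per_phenotype[ph]
            rows.append(
                {
                    "phenotype": ph.value,
                    "true_positive_prob": p.true_positive_prob,
                    "true_negative_prob": p.true_negative_prob,
                    "false_positive_prob": p.false_positive_prob,
                    "n_true": p.n_true,
                    "n_not_true": p.n_not_true,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ROCPoint:
    sampling_time: float
    phenotype: Phenotype
    tpr: float
    fpr: float

    @property
    def youden_j(self) -> float:
        return self.tpr - self.fpr


# ----------------------------------------------------------------------


def confusion_matrix(
    calls: Sequence[PhenotypeCall],
    truths: Mapping[str, Phenotype | str],
) -> ConfusionMatrix:
    """Tally calls against truths keyed by subject id."""
    missing = [c.subject_id for c in calls if c.subject_id not in truths]
    if missing:
        raise KeyError(f"no truth for subject(s): {missing}")
    counts = np.zeros((3, 3), dtype=int)
    for call in calls:
        i = PHENOTYPES.index(coerce_phenotype(truths[call.subject_id]))
        j = PHENOTYPES.index(call.predicted)
        counts[i, j] += 1
    return ConfusionMatrix(counts)


def sensitivity_specificity(matrix: ConfusionMatrix) -> PerformanceSummary:
    """Exact per-phenotype sensitivity and specificity from the counts.

    Rows with zero count yield ``None`` (undefined, flagged) rather than a
    silently imputed value; P(+|−) is formed as the exact float complement of
    P(−|−) so the two always sum to 1.
    """
    c = matrix.counts
    total = int(c.sum())
    out = {}
    for i, ph in enumerate(PHENOTYPES):
        n_true = int(c[i].sum())
        n_not = total - n_true
        tpr = float(Fraction(int(c[i, i]), n_true)) if n_true else None
        if n_not:
            false_pos = int(c[:, i].sum() - c[i, i])
            tnr = float(Fraction(n_not - false_pos, n_not))
            fpr = 1.0 - tnr
        else:
            tnr = fpr = None
        out[ph] = PhenotypePerformance(ph, tpr, tnr, fpr, n_true, n_not)
    return PerformanceSummary(out)


# ----------------------------------------------------------------------


def classify_cohort(
    table: BinnedConditionalTable, cohort: CohortDataset
) -> list[PhenotypeCall]:
    """MAP call per subject at the table's sampling time. Phenotype labels in
    the cohort, if any, are never read — calls from a blinded copy are
    identical."""
    records = cohort.at_time(table.sampling_time).sort_values("subject_id")
    return [
        classify(table, float(row.conc_ng_ml), subject_id=str(row.subject_id))
        for row in records.itertuples(index=False)
    ]


def roc_over_times(
    training: CohortDataset,
    eval_cohort: CohortDataset,
    times: Sequence[float] = (2.0, 4.0, 8.0, 12.0, 24.0),
    **classifier_kwargs,
) -> list[ROCPoint]:
    """One (time, phenotype) ROC point per candidate sampling time.

    The classifier is trained per time on ``training`` only, then applied to
    ``eval_cohort`` (which may be the training set itself for in-sample
    development-style probabilities).
    """
    for t in times:
        for name, ds in (("training", training), ("evaluation", eval_cohort)):
            if not np.isclose(ds.times, t, atol=1e-9).any():
                raise ValueError(f"{name} cohort has no records at {t} h")
    truths = eval_cohort.subject_phenotypes()
    if truths.isna().any():
        raise ValueError("evaluation cohort must carry phenotype truths")
    points = []
    for t in times:
        table = fit_conditional_table(training, t, **classifier_kwargs)
        calls = classify_cohort(table, eval_cohort)
        perf = sensitivity_specificity(confusion_matrix(calls, truths.to_dict()))
        for ph in PHENOTYPES:
            p = perf.per_phenotype[ph]
            points.append(ROCPoint(float(t), ph, p.true_positive_prob, p.false_positive_prob))
    return points


def select_optimal_time(
    roc: Iterable[ROCPoint], target_phenotype: Phenotype = Phenotype.PM
) -> float:
    """Sampling time with maximal Youden J for the target phenotype; ties go
    to the later time."""
    candidates = [p for p in roc if p.phenotype is coerce_phenotype(target_phenotype)]
    if not candidates:
        raise ValueError(f"no ROC points for phenotype {target_phenotype}")
    return max(candidates, key=lambda p: (p.youden_j, p.sampling_time)).sampling_time


def roc_frame(points: Iterable[ROCPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "time_h": p.sampling_time,
                "phenotype": p.phenotype.value,
                "tpr": p.tpr,
                "fpr": p.fpr,
                "youden_j": p.youden_j,
            }
            for p in points
        ]
    )


# ----------------------------------------------------------------------


def evaluate_cohort(
    table: BinnedConditionalTable,
    cohort: CohortDataset,
    truths: Mapping[str, Phenotype | str] | pd.Series | None = None,
) -> tuple[list[PhenotypeCall], ConfusionMatrix | None, PerformanceSummary | None]:
    """Blinded verification: call every subject, then (only if truths are
    supplied) join on subject id and score. The calls are computed before the
    truth mapping is consulted, so they are identical with or without it."""
    calls = classify_cohort(table, cohort)
    if truths is None:
        return calls, None, None
    if isinstance(truths, pd.Series):
        truths = truths.to_dict()
    matrix = confusion_matrix(calls, truths)
    return calls, matrix, sensitivity_specificity(matrix)


def calls_frame(calls: Sequence[PhenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": c.subject_id,
                "predicted": c.predicted.value,
                **{f"p_{ph.value.lower()}": c.posterior[ph] for ph in PHENOTYPES},
                "tie_flag": c.tie_flag,
            }
            for c in calls
        ]
    )
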