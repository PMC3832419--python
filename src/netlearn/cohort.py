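"""Task-level averaging, baseline-relative deviations, and cohort statistics.

Per subject and task, window metrics are averaged into a single pair
``(C_T, L_T)``.  To factor out the large between-subject variability of raw
network characteristics, the learning tasks are expressed as percent
deviations from the same subject's baseline:

    dC% = 100 * (C_task - C_baseline) / C_baseline     (dL% analogously).

Cohort-level inference follows the classical repeated-measures route: a
one-way rm-ANOVA over the three conditions (baseline B, incidental learning
L1, intentional learning L2) with Greenhouse-Geisser and Huynh-Feldt
sphericity corrections, pairwise paired t-tests gated on a significant
omnibus test, and Pearson correlations between the learning-induced
deviations and the subsequent free-recall scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    DegenerateStatisticError,
    IncompleteDesignError,
    ParameterError,
)
from .io import SubjectRecord
from .network import WindowMetrics

__all__ = [
    "TaskMetrics",
    "DeviationRecord",
    "AnovaResult",
    "CohortResult",
    "task_mean",
    "relative_deviation",
    "paired_t_test",
    "rm_anova_sphericity",
    "pearson_correlation",
    "run_cohort",
]

logger = logging.getLogger(__name__)

#: conditions entering the omnibus comparison, in canonical order
CONDITIONS = ("B", "L1", "L2")

#: (deviation variable, recall variable) pairs reported by the cohort analysis
CORRELATION_PAIRS = (
    ("dC_L1", "recall_incidental"),
    ("dC_L2", "recall_intentional"),
    ("dL_L1", "recall_incidental"),
    ("dL_L2", "recall_intentional"),
    ("dC_L2", "recall_incidental"),
)

#: below this Greenhouse-Geisser epsilon the GG-corrected p is flagged primary
GG_PRIMARY_EPSILON = 0.75


@dataclass
class TaskMetrics:
    """Window-averaged network characteristics for one subject and task."""

    subject_id: str
    task: str
    C_task: float
    L_task: float
    n_windows: int


@dataclass
class DeviationRecord:
    """Percent deviation of a learning task from the subject's baseline."""

    subject_id: str
    task: str
    dC_pct: float
    dL_pct: float


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with sphericity corrections."""

    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    epsilon_gg: float
    epsilon_hf: float
    p_gg: float
    p_hf: float

    @property
    def p_primary(self) -> float:
        """GG-corrected p when epsilon_gg < 0.75, else the uncorrected p."""
        return self.p_gg if self.epsilon_gg < GG_PRIMARY_EPSILON else self.p_uncorrected


@dataclass
class CohortResult:
    """All cohort-level outputs of the analysis."""

    task_summary: dict          # task -> {"C_mean": ..., "C_sd": ..., ...}
    deviation_summary: dict     # task -> {"dC_pct_mean": ..., ...}
    group_summary: dict         # group -> task -> summary (secondary table)
    anova_C: AnovaResult
    anova_L: AnovaResult
    pairwise_C: dict            # "B_vs_L1" -> {"t": ..., "p": ...} | {}
    pairwise_L: dict
    correlations: dict          # "dC_L2~recall_intentional" -> {"r":, "p":, "n":}
    n_subjects: int
    excluded_subjects: list = field(default_factory=list)
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def task_mean(metrics: Sequence[WindowMetrics], subject_id: str, task: str
              ) -> TaskMetrics:
    """Arithmetic mean of C and L over a task's windows."""
    if not metrics:
        raise DegenerateInputError(f"no windows for subject {subject_id}, task {task}")
    return TaskMetrics(
        subject_id=subject_id,
        task=task,
        C_task=float(np.mean([m.clustering for m in metrics])),
        L_task=float(np.mean([m.path_length for m in metrics])),
        n_windows=len(metrics),
    )


def relative_deviation(task: TaskMetrics, baseline: TaskMetrics) -> DeviationRecord:
    """Percent deviation of one task's C and L from the baseline values."""
    if baseline.C_task <= 0 or baseline.L_task <= 0:
        raise DegenerateInputError(
            f"subject {task.subject_id}: baseline C or L is not positive")
    return DeviationRecord(
        subject_id=task.subject_id,
        task=task.task,
        dC_pct=100.0 * (task.C_task - baseline.C_task) / baseline.C_task,
        dL_pct=100.0 * (task.L_task - baseline.L_task) / baseline.L_task,
    )


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test; returns ``(t, p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("paired samples must be 1-D and equal length")
    if x.size < 3:
        raise ParameterError(f"need at least 3 pairs, got {x.size}")
    d = x - y
    if np.allclose(d, d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        raise DegenerateStatisticError("zero variance of paired differences")
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)


def pearson_correlation(x: Sequence[float], y: Sequence[float]
                        ) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("samples must be 1-D and equal length")
    if x.size < 3:
        raise ParameterError(f"need at least 3 observations, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateStatisticError("constant input has no defined correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def rm_anova_sphericity(data: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA with GG and HF sphericity corrections.

    ``data`` is an ``(n_subjects, m_conditions)`` matrix of complete cases.
    The F statistic uses the subject-by-condition interaction as error term;
    the Greenhouse-Geisser epsilon is estimated from the covariance matrix of
    the conditions (clamped to ``[1/(m-1), 1]``) and Huynh-Feldt applies the
    usual small-sample correction to it (clamped above at 1).  Corrected
    p-values scale both degrees of freedom by epsilon.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 2:
        raise ParameterError("data must be a subjects x conditions matrix")
    n, m = y.shape
    if m < 2:
        raise ParameterError("need at least 2 conditions")
    if n < 3:
        raise ParameterError(f"need at least 3 subjects, got {n}")
    if not np.isfinite(y).all():
        raise IncompleteDesignError("missing or non-finite cells in the design")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = y - subj_means[:, None] - cond_means[None, :] + grand
    ss_err = np.sum(resid ** 2)
    df1 = m - 1
    df2 = (n - 1) * (m - 1)
    if ss_err <= 0:
        if ss_cond <= 0:
            # every subject flat across conditions: no effect, by convention
            return AnovaResult(F=0.0, df_num=float(df1), df_den=float(df2),
                               p_uncorrected=1.0, epsilon_gg=1.0, epsilon_hf=1.0,
                               p_gg=1.0, p_hf=1.0)
        raise DegenerateStatisticError("zero error sum of squares")
    F = (ss_cond / df1) / (ss_err / df2)
    p_unc = float(stats.f.sf(F, df1, df2))

    # Greenhouse-Geisser epsilon from the (sample) covariance of conditions
    S = np.cov(y, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    mean_diag = np.trace(S) / m
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (m * (mean_diag - mean_all)) ** 2
    den = (m - 1) * (np.sum(S ** 2) - 2 * m * np.sum(row_means ** 2)
                     + m ** 2 * mean_all ** 2)
    if den <= 0:
        eps_gg = 1.0  # perfectly spherical (e.g. m == 2)
    else:
        eps_gg = float(num / den)
    eps_gg = float(np.clip(eps_gg, 1.0 / (m - 1), 1.0))

    eps_hf = (n * df1 * eps_gg - 2.0) / (df1 * (n - 1 - df1 * eps_gg))
    eps_hf = float(np.clip(eps_hf, 1.0 / (m - 1), 1.0))

    p_gg = float(stats.f.sf(F, df1 * eps_gg, df2 * eps_gg))
    p_hf = float(stats.f.sf(F, df1 * eps_hf, df2 * eps_hf))
    return AnovaResult(
        F=float(F), df_num=float(df1), df_den=float(df2), p_uncorrected=p_unc,
        epsilon_gg=eps_gg, epsilon_hf=eps_hf, p_gg=p_gg, p_hf=p_hf,
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _summary(values: np.ndarray) -> dict:
    return {"mean": float(np.mean(values)), "sd": float(np.std(values, ddof=1))}


def run_cohort(task_metrics: Iterable[TaskMetrics],
               subjects: Sequence[SubjectRecord],
               alpha: float = 0.05) -> CohortResult:
    """Assemble the full cohort analysis.

    Subjects lacking any of the B/L1/L2 metrics or a behavioral row are
    excluded with a logged warning.  Headline statistics merge the control
    and patient groups; a group-stratified summary is retained as a secondary
    table.  Pairwise paired t-tests are run only when the omnibus ANOVA is
    significant at ``alpha`` (primary p), and the five deviation-vs-recall
    Pearson correlations are always reported.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0,1), got {alpha}")
    by_subject: dict[str, dict[str, TaskMetrics]] = {}
    for tm in task_metrics:
        by_subject.setdefault(tm.subject_id, {})[tm.task] = tm
    behavior = {s.subject_id: s for s in subjects}

    complete, excluded = [], []
    for sid in sorted(set(by_subject) | set(behavior)):
        tasks = by_subject.get(sid, {})
        if sid in behavior and all(c in tasks for c in CONDITIONS):
            complete.append(sid)
        else:
            missing = [c for c in CONDITIONS if c not in tasks]
            why = f"missing tasks {missing}" if missing else "missing behavior row"
            logger.warning("excluding subject %s: %s", sid, why)
            excluded.append(sid)
    if len(complete) < 3:
        raise DegenerateInputError(
            f"only {len(complete)} complete subjects; need at least 3")

    C = np.array([[by_subject[s][c].C_task for c in CONDITIONS] for s in complete])
    L = np.array([[by_subject[s][c].L_task for c in CONDITIONS] for s in complete])
    deviations = {
        s: {task: relative_deviation(by_subject[s][task], by_subject[s]["B"])
            for task in ("L1", "L2")}
        for s in complete
    }

    task_summary = {
        cond: {"C": _summary(C[:, i]), "L": _summary(L[:, i])}
        for i, cond in enumerate(CONDITIONS)
    }
    deviation_summary = {
        task: {
            "dC_pct": _summary(np.array([deviations[s][task].dC_pct for s in complete])),
            "dL_pct": _summary(np.array([deviations[s][task].dL_pct for s in complete])),
        }
        for task in ("L1", "L2")
    }
    group_summary: dict[str, dict] = {}
    for group in ("control", "patient"):
        members = [i for i, s in enumerate(complete) if behavior[s].group == group]
        if len(members) >= 2:
            group_summary[group] = {
                cond: {"C": _summary(C[members][:, i]), "L": _summary(L[members][:, i])}
                for i, cond in enumerate(CONDITIONS)
            }
            group_summary[group]["n"] = len(members)

    anova_C = rm_anova_sphericity(C)
    anova_L = rm_anova_sphericity(L)

    def pairwise(mat: np.ndarray, omnibus: AnovaResult) -> dict:
        if omnibus.p_primary >= alpha:
            return {}
        out = {}
        for i in range(len(CONDITIONS)):
            for j in range(i + 1, len(CONDITIONS)):
                t, p = paired_t_test(mat[:, j], mat[:, i])
                out[f"{CONDITIONS[i]}_vs_{CONDITIONS[j]}"] = {"t": t, "p": p}
        return out

    variables: Mapping[str, np.ndarray] = {
        "dC_L1": np.array([deviations[s]["L1"].dC_pct for s in complete]),
        "dC_L2": np.array([deviations[s]["L2"].dC_pct for s in complete]),
        "dL_L1": np.array([deviations[s]["L1"].dL_pct for s in complete]),
        "dL_L2": np.array([deviations[s]["L2"].dL_pct for s in complete]),
        "recall_incidental": np.array(
            [behavior[s].recall_incidental for s in complete], dtype=float),
        "recall_intentional": np.array(
            [behavior[s].recall_intentional for s in complete], dtype=float),
    }
    correlations = {}
    for dev_var, recall_var in CORRELATION_PAIRS:
        try:
            r, p = pearson_correlation(variables[dev_var], variables[recall_var])
        except DegenerateStatisticError:
            logger.warning("correlation %s~%s undefined (constant input)",
                           dev_var, recall_var)
            r = p = float("nan")
        correlations[f"{dev_var}~{recall_var}"] = {"r": r, "p": p, "n": len(complete)}

    return CohortResult(
        task_summary=task_summary,
        deviation_summary=deviation_summary,
        group_summary=group_summary,
        anova_C=anova_C,
        anova_L=anova_L,
        pairwise_C=pairwise(C, anova_C),
        pairwise_L=pairwise(L, anova_L),
        correlations=correlations,
        n_subjects=len(complete),
        excluded_subjects=excluded,
        alpha=alpha,
    )
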