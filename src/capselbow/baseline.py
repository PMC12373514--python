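"""Baseline-severity checks: does initial symptom load predict outcome?

Two analyses mirror the usual sanity checks on a responder analysis:

* correlation of the baseline total with relative improvement
  ``1 - (timepoint total / baseline total)`` at end of treatment and at
  follow-up (both Spearman and Pearson are emitted, since either may be
  reported in practice);
* a Mann-Whitney comparison of baseline totals between subjects whose
  follow-up total is lower than at end of treatment (IMPROVED) and those
  whose is higher (WORSENED). Exact ties (fup == post) are assigned to
  WORSENED — the conservative side for a claimed improvement effect —
  and logged.

The Mann-Whitney p is exact (full enumeration) whenever both groups have
at most 12 observations and the pooled values are tie-free; otherwise the
normal approximation with tie and continuity corrections is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Arm, Cohort
from .clusters import CorrelationResult, correlate

logger = logging.getLogger(__name__)

__all__ = [
    "MannWhitneyResult",
    "TrajectorySplit",
    "baseline_outcome_correlation",
    "split_by_fup_trajectory",
    "mann_whitney",
    "BaselineSeverityModel",
    "BaselineSeverityResults",
    "EXACT_LIMIT",
]

#: largest per-group size for which the exact null distribution is used
EXACT_LIMIT = 12


def baseline_outcome_correlation(cohort: Cohort,
                                 arm: Arm | str | None = Arm.ACTIVE,
                                 timepoint: str = "post",
                                 method: str = "spearman") -> CorrelationResult:
    """Correlate baseline total with improvement 1 - timepoint/pre."""
    if timepoint not in ("post", "fup"):
        raise ValueError("timepoint must be 'post' or 'fup'")
    from .elbow import normalize_cohort

    norm = normalize_cohort(cohort, arm)
    pre_by_id = {r.participant_id: r.pre.total for r in cohort.arm(arm)}
    baseline = [pre_by_id[o.participant_id] for o in norm.outcomes]
    ratio = [o.post_ratio if timepoint == "post" else o.fup_ratio
             for o in norm.outcomes]
    improvement = [1.0 - v for v in ratio]
    return correlate(baseline, improvement, method=method,
                     x_label="baseline total",
                     y_label=f"improvement at {timepoint}")


@dataclass
class TrajectorySplit:
    """Baseline totals split by follow-up trajectory."""

    improved: np.ndarray   # baselines of subjects with fup total < post total
    worsened: np.ndarray   # fup total > post total, plus exact ties
    n_ties: int
    degenerate: bool       # one of the groups is empty

    @property
    def n_improved(self) -> int:
        return len(self.improved)

    @property
    def n_worsened(self) -> int:
        return len(self.worsened)


def split_by_fup_trajectory(cohort: Cohort,
                            arm: Arm | str | None = Arm.ACTIVE
                            ) -> TrajectorySplit:
    """Partition baseline totals by whether follow-up beat end of treatment.

    Records missing POST or FUP are skipped; exact ties go to WORSENED and
    are counted in ``n_ties``. ``degenerate`` flags an empty group, in
    which case the two-sample comparison is not meaningful.
    """
    improved, worsened = [], []
    ties = 0
    for rec in cohort.arm(arm):
        if rec.post is None or rec.fup is None:
            continue
        if rec.fup.total < rec.post.total:
            improved.append(rec.pre.total)
        else:
            if rec.fup.total == rec.post.total:
                ties += 1
            worsened.append(rec.pre.total)
    if ties:
        logger.info("split_by_fup_trajectory: %d exact ties assigned to "
                    "WORSENED", ties)
    split = TrajectorySplit(improved=np.array(improved, dtype=float),
                            worsened=np.array(worsened, dtype=float),
                            n_ties=ties,
                            degenerate=(not improved or not worsened))
    if split.degenerate:
        logger.warning("split_by_fup_trajectory: one group is empty; "
                       "two-sample tests are skipped")
    return split


@dataclass(frozen=True)
class MannWhitneyResult:
    """Mann-Whitney U with the mode of p-value computation used."""

    u: float
    n1: int
    n2: int
    p_two_sided: float
    mode: str   # "exact" | "normal_approx"


def mann_whitney(group1: Sequence[float], group2: Sequence[float]
                 ) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is the rank-sum statistic of ``group1`` (mid-ranks on ties). The p
    is exact by full enumeration when both groups have <= 12 values and
    the pooled sample is tie-free; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([g1, g2])
    tie_free = len(np.unique(pooled)) == len(pooled)
    exact = tie_free and len(g1) <= EXACT_LIMIT and len(g2) <= EXACT_LIMIT
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic), n1=len(g1), n2=len(g2),
                             p_two_sided=float(res.pvalue),
                             mode="exact" if exact else "normal_approx")


# --------------------------------------------------------------------------
# model / results interface

class BaselineSeverityModel:
    """Does baseline severity predict treatment outcome for one arm?"""

    def __init__(self, data, arm: Arm | str | None = Arm.ACTIVE):
        if not isinstance(data, Cohort):
            data = Cohort.from_dataframe(data)
        self.cohort = data
        self.arm = arm

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "BaselineSeverityModel":
        return cls(Cohort.from_dataframe(df), **kwargs)

    def fit(self) -> "BaselineSeverityResults":
        correlations = {
            (tp, method): baseline_outcome_correlation(
                self.cohort, self.arm, timepoint=tp, method=method)
            for tp in ("post", "fup")
            for method in ("spearman", "pearson")
        }
        split = split_by_fup_trajectory(self.cohort, self.arm)
        mw = None if split.degenerate else mann_whitney(split.improved,
                                                        split.worsened)
        return BaselineSeverityResults(self, correlations, split, mw)


class BaselineSeverityResults:
    def __init__(self, model, correlations, split: TrajectorySplit,
                 mann_whitney_result: Optional[MannWhitneyResult]):
        self.model = model
        self.correlations = correlations
        self.split = split
        self.mann_whitney = mann_whitney_result

    def summary(self) -> str:
        lines = ["Baseline severity checks", "=" * 60]
        for (tp, method), res in self.correlations.items():
            lines.append(f"baseline vs improvement at {tp:<4s} ({method}): "
                         f"r={res.r:+.3f}  p={res.p_asymptotic:.3g}  n={res.n}")
        lines.append("-" * 60)
        s = self.split
        lines.append(f"follow-up improved n={s.n_improved}, "
                     f"worsened n={s.n_worsened} (ties to worsened: {s.n_ties})")
        if self.mann_whitney is None:
            lines.append("Mann-Whitney: skipped (one group empty)")
        else:
            m = self.mann_whitney
            lines.append(f"Mann-Whitney U={m.u:.1f}  p={m.p_two_sided:.3g}  "
                         f"({m.mode})")
        lines.append("=" * 60)
        return "\n".join(lines)
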