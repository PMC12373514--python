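"""Cluster-wise association of symptom-cluster change with overall change.

Each CAPS-5 cluster's relative change (post/pre and fup/pre of the cluster
subtotal) is correlated with the total score's relative change at three
comparisons:

* ``post_vs_post_total`` — cluster post/pre vs total post/pre (which
  cluster co-moves most with overall improvement at end of treatment);
* ``fup_vs_fup_total`` — cluster fup/pre vs total fup/pre (same at
  follow-up);
* ``postcluster_vs_fup_total`` — cluster post/pre vs total fup/pre (which
  end-of-treatment cluster change best predicts the follow-up outcome).

Spearman rank correlation is the headline method (robust to the ratio
scale); Pearson is available side by side. Significance comes both from
the asymptotic two-sided p and from a pairs bootstrap (percentile CI and
an add-one-smoothed two-sided tail probability of the null value 0 under
the resampled coefficient distribution).

Clusters whose baseline subtotal is 0 (possible for the two-item avoidance
cluster) have undefined ratios and are excluded pairwise, with a log line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Arm, Cohort
from .elbow import normalize_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterRatios",
    "CorrelationResult",
    "AssociationMatrix",
    "ShamCounts",
    "cluster_ratios",
    "correlate",
    "bootstrap_inference",
    "association_matrices",
    "sham_threshold_count",
    "ClusterAssociationModel",
    "ClusterAssociationResults",
    "COMPARISONS",
]

CLUSTERS = ("B", "C", "D", "E")
COMPARISONS = ("post_vs_post_total", "fup_vs_fup_total", "postcluster_vs_fup_total")


@dataclass(frozen=True)
class ClusterRatios:
    """Per-cluster post/pre and fup/pre ratios for one subject.

    Ratios are NaN (and flagged undefined) for a cluster whose baseline
    subtotal is 0.
    """

    participant_id: str
    post_ratio: dict    # cluster -> float (NaN if undefined)
    fup_ratio: dict
    defined: dict       # cluster -> bool


def cluster_ratios(cohort: Cohort, arm: Arm | str | None = Arm.ACTIVE
                   ) -> list[ClusterRatios]:
    """Cluster-level change ratios, same retention rules as normalization."""
    retained_ids = {o.participant_id for o in normalize_cohort(cohort, arm).outcomes}
    out: list[ClusterRatios] = []
    n_undef = 0
    for rec in cohort.arm(arm):
        if rec.participant_id not in retained_ids:
            continue
        post_r, fup_r, defined = {}, {}, {}
        for cl, attr in zip(CLUSTERS, "bcde"):
            pre_v = getattr(rec.pre, attr)
            if pre_v == 0:
                post_r[cl] = math.nan
                fup_r[cl] = math.nan
                defined[cl] = False
                n_undef += 1
                continue
            post_r[cl] = getattr(rec.post, attr) / pre_v
            fup_r[cl] = getattr(rec.fup, attr) / pre_v
            defined[cl] = True
        out.append(ClusterRatios(rec.participant_id, post_r, fup_r, defined))
    if n_undef:
        logger.info("cluster_ratios: %d cluster ratios undefined (pre=0), "
                    "excluded pairwise", n_undef)
    return out


@dataclass
class CorrelationResult:
    """A correlation with asymptotic and (optional) bootstrap inference."""

    x_label: str
    y_label: str
    method: str          # "spearman" | "pearson"
    n: int
    r: float
    p_asymptotic: float
    p_bootstrap: Optional[float] = None
    ci95: Optional[tuple[float, float]] = None
    undefined: bool = False   # zero variance in x or y

    def to_dict(self) -> dict:
        return {
            "x": self.x_label, "y": self.y_label, "method": self.method,
            "n": self.n, "r": None if self.undefined else self.r,
            "p_asymptotic": None if self.undefined else self.p_asymptotic,
            "p_bootstrap": self.p_bootstrap,
            "ci95": list(self.ci95) if self.ci95 else None,
            "undefined": self.undefined,
        }


def correlate(x: Sequence[float], y: Sequence[float], method: str = "spearman",
              x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Spearman (mid-rank) or Pearson correlation with asymptotic p.

    Requires at least 3 complete pairs; a variable with zero variance
    yields a result marked ``undefined`` rather than propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(x_label, y_label, method, n,
                                 math.nan, math.nan, undefined=True)
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(x_label, y_label, method, n, float(r), float(p))


def _boot_corr(x: np.ndarray, y: np.ndarray, method: str, b: int,
               rng: np.random.Generator) -> np.ndarray:
    """Coefficients over b pair resamples, vectorized."""
    n = len(x)
    idx = rng.integers(0, n, size=(b, n))
    xs, ys = x[idx], y[idx]
    if method == "spearman":
        xs = stats.rankdata(xs, axis=1)
        ys = stats.rankdata(ys, axis=1)
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    num = (xs * ys).sum(axis=1)
    den = np.sqrt((xs ** 2).sum(axis=1) * (ys ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return r[~np.isnan(r)]  # degenerate resamples (zero variance) dropped


def bootstrap_inference(x: Sequence[float], y: Sequence[float],
                        method: str = "spearman", b: int = 1000,
                        seed: Optional[int] = None
                        ) -> tuple[float, tuple[float, float]]:
    """Pairs-bootstrap p and percentile 95% CI for a correlation.

    p is the add-one-smoothed two-sided tail probability of 0 under the
    resampled coefficient distribution:
    ``min(1, 2 * min(#{r* <= 0}, #{r* >= 0}) + 1) / (B + 1)``.
    """
    if b < 100:
        raise ValueError("b must be >= 100 for stable tails")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    rng = np.random.default_rng(seed)
    r_star = _boot_corr(x, y, method, b, rng)
    b_eff = len(r_star)
    lo = int(np.sum(r_star <= 0.0))
    hi = int(np.sum(r_star >= 0.0))
    p = min(1.0, 2.0 * (1 + min(lo, hi)) / (1 + b_eff))
    ci = (float(np.percentile(r_star, 2.5)), float(np.percentile(r_star, 97.5)))
    return p, ci


@dataclass
class AssociationMatrix:
    """One comparison's CorrelationResult per cluster (exactly four)."""

    comparison: str
    results: dict  # cluster letter -> CorrelationResult

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cl in CLUSTERS:
            d = self.results[cl].to_dict()
            d["comparison"] = self.comparison
            d["cluster"] = cl
            rows.append(d)
        return pd.DataFrame(rows)


def association_matrices(cohort: Cohort, arm: Arm | str | None = Arm.ACTIVE,
                         method: str = "spearman", b: int = 1000,
                         seed: Optional[int] = None,
                         fup_total: str = "fup_pre"
                         ) -> dict[str, AssociationMatrix]:
    """The three cluster-vs-total association matrices with bootstrap
    inference.

    ``fup_total`` selects the follow-up total ratio for the predictive
    comparison: ``"fup_pre"`` (follow-up normalized to baseline, the
    default) or ``"fup_post"`` (normalized to end of treatment).
    """
    if fup_total not in ("fup_pre", "fup_post"):
        raise ValueError("fup_total must be 'fup_pre' or 'fup_post'")
    norm = {o.participant_id: o for o in normalize_cohort(cohort, arm).outcomes}
    ratios = cluster_ratios(cohort, arm)
    total_post = np.array([norm[r.participant_id].post_ratio for r in ratios])
    total_fup = np.array([norm[r.participant_id].fup_ratio for r in ratios])
    if fup_total == "fup_post":
        total_fup = total_fup / total_post
    rng = np.random.default_rng(seed)

    def column(which: str, cl: str) -> np.ndarray:
        src = [getattr(r, which)[cl] for r in ratios]
        return np.asarray(src, dtype=float)

    spec = {
        "post_vs_post_total": ("post_ratio", total_post, "total post/pre"),
        "fup_vs_fup_total": ("fup_ratio", total_fup if fup_total == "fup_pre"
                             else total_fup, "total fup ratio"),
        "postcluster_vs_fup_total": ("post_ratio", total_fup, "total fup ratio"),
    }
    # comparison (b) always uses fup/pre on both axes
    if fup_total == "fup_post":
        tf_pre = np.array([norm[r.participant_id].fup_ratio for r in ratios])
        spec["fup_vs_fup_total"] = ("fup_ratio", tf_pre, "total fup/pre")

    out: dict[str, AssociationMatrix] = {}
    for comp, (which, total, total_label) in spec.items():
        results = {}
        for cl in CLUSTERS:
            xcol = column(which, cl)
            res = correlate(xcol, total, method=method,
                            x_label=f"cluster {cl} {which}",
                            y_label=total_label)
            if not res.undefined:
                sub_seed = int(rng.integers(0, 2 ** 31 - 1))
                res.p_bootstrap, res.ci95 = bootstrap_inference(
                    xcol, total, method=method, b=b, seed=sub_seed)
            results[cl] = res
        out[comp] = AssociationMatrix(comparison=comp, results=results)
    return out


@dataclass(frozen=True)
class ShamCounts:
    """Descriptive sham-arm counts around the improvement threshold."""

    n_sham: int
    deep_responders: int          # post/pre < 1 - pct/100
    cluster_c_improved: int       # avoidance subtotal strictly lower at POST
    cluster_c_attenuated: int     # of those, higher again at FUP


def sham_threshold_count(cohort: Cohort, improvement_pct: float = 35.0
                         ) -> ShamCounts:
    """Count sham subjects beyond the improvement threshold and the
    behavior of their avoidance-cluster change."""
    records = [r for r in cohort.arm(Arm.SHAM)
               if r.pre.total > 0 and r.post is not None]
    if not records:
        raise ValueError("sham arm is empty (or has no usable records)")
    cut = 1.0 - improvement_pct / 100.0
    deep = sum(1 for r in records if r.post.total / r.pre.total < cut)
    c_improved = [r for r in records if r.post.c < r.pre.c]
    c_atten = sum(1 for r in c_improved
                  if r.fup is not None and r.fup.c > r.post.c)
    return ShamCounts(n_sham=len(records), deep_responders=deep,
                      cluster_c_improved=len(c_improved),
                      cluster_c_attenuated=c_atten)


# --------------------------------------------------------------------------
# model / results interface

class ClusterAssociationModel:
    """Cluster-vs-total association analysis for one arm of a cohort."""

    def __init__(self, data, arm: Arm | str | None = Arm.ACTIVE,
                 fup_total: str = "fup_pre"):
        if not isinstance(data, Cohort):
            data = Cohort.from_dataframe(data)
        self.cohort = data
        self.arm = arm
        self.fup_total = fup_total

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "ClusterAssociationModel":
        return cls(Cohort.from_dataframe(df), **kwargs)

    def fit(self, method: str = "spearman", b: int = 1000,
            seed: Optional[int] = None) -> "ClusterAssociationResults":
        matrices = association_matrices(self.cohort, self.arm, method=method,
                                        b=b, seed=seed,
                                        fup_total=self.fup_total)
        return ClusterAssociationResults(self, matrices, method=method)


class ClusterAssociationResults:
    def __init__(self, model: ClusterAssociationModel,
                 matrices: dict[str, AssociationMatrix], method: str):
        self.model = model
        self.matrices = matrices
        self.method = method

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([m.to_frame() for m in self.matrices.values()],
                         ignore_index=True)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [f"Cluster associations ({self.method})", "=" * 72]
        for comp in COMPARISONS:
            lines.append(comp)
            sub = df[df.comparison == comp]
            for _, row in sub.iterrows():
                if row["undefined"]:
                    lines.append(f"  cluster {row.cluster}: undefined "
                                 "(zero variance)")
                else:
                    ci = row["ci95"]
                    ci_s = f"[{ci[0]:+.2f}, {ci[1]:+.2f}]" if ci else "-"
                    lines.append(
                        f"  cluster {row.cluster}: r={row.r:+.3f}  "
                        f"p={row.p_asymptotic:.2g}  "
                        f"p_boot={row.p_bootstrap:.2g}  ci95={ci_s}  "
                        f"n={row.n}")
            lines.append("-" * 72)
        return "\n".join(lines)
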