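"""Synthetic CAPS-5 cohort generators.

Two engines produce cohorts with the statistical structure the threshold
analysis assumes, since participant-level trial data of this kind are
typically not public:

* a **parametric planted-threshold engine** (:func:`generate_planted_cohort`)
  that draws baseline totals from a truncated normal, end-of-treatment
  ratios from a configurable distribution, and makes the probability of
  *further* improvement at follow-up depend on whether the end-of-treatment
  ratio crossed a planted threshold ``theta`` — ground truth for
  parameter-recovery experiments;

* a **mechanistic bistable engine** (:func:`generate_bistable_cohort`)
  integrating an overdamped Langevin particle in a quartic double well
  ``U(x) = h (x^2 - 1)^2`` (healthy well at x = -1, pathological well at
  x = +1). Treatment is a constant bias ``d`` subtracted from the drift
  during the treatment phase only; a push strong enough to carry the state
  over the barrier yields a lasting transition (sustained improvement),
  a weaker push lets the state roll back — the dynamical picture behind a
  threshold effect in treatment response.

A third, deliberately structure-free generator
(:func:`generate_null_cohort`) draws follow-up ratios independently of
end-of-treatment ratios; it is the null model under which the permutation
test must hold its size.

All generators emit :class:`~capselbow.cohort.Cohort` objects that pass
``validate_cohort`` by construction; integer totals are decomposed into the
four cluster subtotals by largest-remainder rounding of weight-proportional
shares (weights default to the CAPS-5 item counts 5:2:7:6).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import (
    Arm,
    CapsScores,
    Cohort,
    ParticipantRecord,
    CLUSTER_ITEM_COUNTS,
    CLUSTER_MAX,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DistSpec",
    "PlantedConfig",
    "BistableParams",
    "Trajectory",
    "generate_planted_cohort",
    "generate_null_cohort",
    "generate_null_outcomes",
    "simulate_bistable_trajectory",
    "generate_bistable_cohort",
    "critical_push",
    "transition_probability",
    "map_state_to_caps",
    "decompose_total",
    "WELL_MARGIN",
    "DT_STABILITY_FACTOR",
]

#: |x| beyond which a terminal state is assigned to a well (else UNDECIDED)
WELL_MARGIN = 0.2

#: Euler-Maruyama step bound: require dt <= DT_STABILITY_FACTOR / h.
#: The stiffest curvature on the relevant range |x| <~ 1.5 is U'' ~ 23 h,
#: so dt = 0.05 / h keeps dt * U'' well below 1.
DT_STABILITY_FACTOR = 0.05


# --------------------------------------------------------------------------
# distribution specs (JSON-compatible)

@dataclass(frozen=True)
class DistSpec:
    """A small, serializable family of scalar distributions.

    kinds: ``truncnorm`` (mean, sd, low, high), ``uniform`` (low, high),
    ``constant`` (value).
    """

    kind: str
    mean: float = 0.0
    sd: float = 1.0
    low: float = 0.0
    high: float = 1.0
    value: float = 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "truncnorm":
            a = (self.low - self.mean) / self.sd
            b = (self.high - self.mean) / self.sd
            return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                       size=size, random_state=rng)
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size)
        if self.kind == "constant":
            return np.full(size, float(self.value))
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "truncnorm":
            d.update(mean=self.mean, sd=self.sd, low=self.low, high=self.high)
        elif self.kind == "uniform":
            d.update(low=self.low, high=self.high)
        else:
            d.update(value=self.value)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistSpec":
        return cls(**d)


# --------------------------------------------------------------------------
# cluster decomposition

_CLUSTERS = ("B", "C", "D", "E")
DEFAULT_CLUSTER_WEIGHTS = tuple(
    CLUSTER_ITEM_COUNTS[c] / sum(CLUSTER_ITEM_COUNTS.values()) for c in _CLUSTERS
)


def decompose_total(total: int, weights: Sequence[float] = DEFAULT_CLUSTER_WEIGHTS
                    ) -> tuple[int, int, int, int]:
    """Split an integer total into four cluster subtotals.

    Weight-proportional shares are rounded by the largest-remainder rule so
    the subtotals sum to ``total`` exactly. With weights proportional to
    the item counts the per-cluster maxima (20/8/28/24) can never be
    exceeded for totals in [0, 80].
    """
    w = np.asarray(weights, dtype=float)
    if w.min() < 0 or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    shares = total * w
    base = np.floor(shares).astype(int)
    short = int(total - base.sum())
    if short:
        order = np.argsort(-(shares - base), kind="stable")
        base[order[:short]] += 1
    for c, v in zip(_CLUSTERS, base):
        if v > CLUSTER_MAX[c]:
            raise ValueError(f"decomposition exceeds cluster {c} max: {v}")
    return tuple(int(v) for v in base)


def _make_scores(total: int, weights: Sequence[float]) -> CapsScores:
    b, c, d, e = decompose_total(int(total), weights)
    return CapsScores(int(total), b, c, d, e)


# --------------------------------------------------------------------------
# planted-threshold generator

@dataclass
class PlantedConfig:
    """Configuration of the parametric planted-threshold generator.

    Baseline moments default to the pooled two-arm values of the trial this
    design emulates (total ~ 43.8 +/- 9.1, truncated to [23, 80], i.e. at
    least moderate severity on the 0-80 scale). ``theta`` is the planted
    end-of-treatment ratio threshold: subjects with post/pre < theta
    improve further at follow-up with probability ``p_sustain_below``,
    others with ``p_sustain_above``.
    """

    n_active: int = 28
    n_sham: int = 28
    baseline_mean: float = 43.8
    baseline_sd: float = 9.1
    baseline_range: tuple[float, float] = (23.0, 80.0)
    theta: float = 0.65
    p_sustain_below: float = 0.9
    p_sustain_above: float = 0.2
    active_improvement_dist: DistSpec = field(
        default_factory=lambda: DistSpec("truncnorm", mean=0.70, sd=0.25,
                                         low=0.05, high=1.2))
    sham_improvement_dist: DistSpec = field(
        default_factory=lambda: DistSpec("truncnorm", mean=1.0, sd=0.08,
                                         low=0.7, high=1.2))
    fup_step_dist: DistSpec = field(
        default_factory=lambda: DistSpec("truncnorm", mean=0.12, sd=0.05,
                                         low=0.02, high=0.4))
    cluster_weights: tuple[float, float, float, float] = DEFAULT_CLUSTER_WEIGHTS
    seed: int = 0

    def validate(self) -> None:
        if self.n_active < 0 or self.n_sham < 0:
            raise ValueError("arm sizes must be nonnegative")
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must lie in (0, 1)")
        for p in (self.p_sustain_below, self.p_sustain_above):
            if not (0.0 <= p <= 1.0):
                raise ValueError("sustain probabilities must lie in [0, 1]")
        lo, hi = self.baseline_range
        if not (lo <= self.baseline_mean <= hi):
            raise ValueError("baseline_range excludes baseline_mean")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        if min(self.cluster_weights) < 0 or sum(self.cluster_weights) <= 0:
            raise ValueError("cluster_weights must be nonnegative, positive sum")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("active_improvement_dist", "sham_improvement_dist", "fup_step_dist"):
            d[k] = getattr(self, k).to_dict()
        return d


def _sample_baseline(rng: np.random.Generator, n: int, mean: float, sd: float,
                     lo: float, hi: float) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    pre = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(pre), max(1, lo), hi).astype(int)


def _fup_totals(rng: np.random.Generator, pre: np.ndarray, post: np.ndarray,
                sustain: np.ndarray, step_dist: DistSpec) -> np.ndarray:
    """Follow-up totals: strictly below post when sustaining, at/above else."""
    step = step_dist.sample(rng, len(pre))
    down = np.maximum(1, np.rint(step * pre)).astype(int)
    up = np.rint(0.5 * step * pre).astype(int)  # may be 0 -> exact tie, not improved
    fup = np.where(sustain, post - down, post + up)
    return np.clip(fup, 1, 80).astype(int)


def generate_planted_cohort(config: PlantedConfig) -> Cohort:
    """Generate a two-arm cohort with a planted follow-up threshold effect.

    Active arm: post/pre drawn from ``active_improvement_dist``; follow-up
    improves further (strictly) with probability ``p_sustain_below`` or
    ``p_sustain_above`` according to post/pre vs ``theta``. Sham arm:
    post/pre near 1, except one planted deep responder per 28 sham
    subjects whose improvement attenuates at follow-up. Deterministic for
    fixed config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[ParticipantRecord] = []

    # ---- active arm
    n = config.n_active
    if n:
        pre = _sample_baseline(rng, n, config.baseline_mean, config.baseline_sd,
                               *config.baseline_range)
        ratio = np.clip(config.active_improvement_dist.sample(rng, n), 0.02, 1.2)
        post = np.clip(np.rint(ratio * pre), 1, 80).astype(int)
        below = (post / pre) < config.theta
        p = np.where(below, config.p_sustain_below, config.p_sustain_above)
        sustain = rng.random(n) < p
        fup = _fup_totals(rng, pre, post, sustain, config.fup_step_dist)
        for i in range(n):
            records.append(ParticipantRecord(
                participant_id=f"A{i + 1:03d}", arm=Arm.ACTIVE,
                pre=_make_scores(pre[i], config.cluster_weights),
                post=_make_scores(post[i], config.cluster_weights),
                fup=_make_scores(fup[i], config.cluster_weights)))

    # ---- sham arm
    m = config.n_sham
    if m:
        pre = _sample_baseline(rng, m, config.baseline_mean, config.baseline_sd,
                               *config.baseline_range)
        ratio = np.clip(config.sham_improvement_dist.sample(rng, m), 0.02, 1.2)
        n_deep = int(round(m / 28))
        deep_idx = rng.choice(m, size=min(n_deep, m), replace=False)
        ratio[deep_idx] = rng.uniform(0.40, 0.60, size=len(deep_idx))
        post = np.clip(np.rint(ratio * pre), 1, 80).astype(int)
        below = (post / pre) < config.theta
        p = np.where(below, config.p_sustain_below, config.p_sustain_above)
        sustain = rng.random(m) < p
        sustain[deep_idx] = False  # planted deep sham responders attenuate
        fup = _fup_totals(rng, pre, post, sustain, config.fup_step_dist)
        for i in range(m):
            records.append(ParticipantRecord(
                participant_id=f"S{i + 1:03d}", arm=Arm.SHAM,
                pre=_make_scores(pre[i], config.cluster_weights),
                post=_make_scores(post[i], config.cluster_weights),
                fup=_make_scores(fup[i], config.cluster_weights)))

    return Cohort(records=records,
                  metadata={"generator": "planted", "config": config.to_dict()})


def generate_null_outcomes(n: int, seed: int,
                           post_dist: DistSpec | None = None,
                           fup_dist: DistSpec | None = None) -> list:
    """n independent (post/pre, fup/pre) ratio pairs with fup independent
    of post: the exchangeable null of the threshold permutation test,
    expressed directly on the ratio scale the test operates on.

    Unlike :func:`generate_null_cohort` there is no rounding through
    integer scores, so the distance statistic has (almost surely) no
    exact ties across permutations and the counting p-value is exact.
    """
    from .elbow import NormalizedOutcome

    post_dist = post_dist or DistSpec("truncnorm", mean=0.70, sd=0.25,
                                      low=0.05, high=1.2)
    fup_dist = fup_dist or DistSpec("truncnorm", mean=0.75, sd=0.30,
                                    low=0.05, high=1.4)
    rng = np.random.default_rng(seed)
    post = post_dist.sample(rng, n)
    fup = fup_dist.sample(rng, n)
    return [NormalizedOutcome(f"N{i + 1:03d}", Arm.ACTIVE,
                              float(post[i]), float(fup[i]))
            for i in range(n)]


def generate_null_cohort(
    n: int,
    seed: int,
    baseline_mean: float = 43.8,
    baseline_sd: float = 9.1,
    baseline_range: tuple[float, float] = (23.0, 80.0),
    post_dist: DistSpec | None = None,
    fup_dist: DistSpec | None = None,
    cluster_weights: Sequence[float] = DEFAULT_CLUSTER_WEIGHTS,
) -> Cohort:
    """Single-arm cohort in which fup/pre is independent of post/pre.

    Post and follow-up ratios are independent draws, so the improvement
    flag carries no information about end-of-treatment depth: the null
    model of the threshold permutation test.
    """
    post_dist = post_dist or DistSpec("truncnorm", mean=0.70, sd=0.25,
                                      low=0.05, high=1.2)
    fup_dist = fup_dist or DistSpec("truncnorm", mean=0.75, sd=0.30,
                                    low=0.05, high=1.4)
    rng = np.random.default_rng(seed)
    pre = _sample_baseline(rng, n, baseline_mean, baseline_sd, *baseline_range)
    post = np.clip(np.rint(post_dist.sample(rng, n) * pre), 1, 80).astype(int)
    fup = np.clip(np.rint(fup_dist.sample(rng, n) * pre), 1, 80).astype(int)
    records = [
        ParticipantRecord(
            participant_id=f"N{i + 1:03d}", arm=Arm.ACTIVE,
            pre=_make_scores(pre[i], cluster_weights),
            post=_make_scores(post[i], cluster_weights),
            fup=_make_scores(fup[i], cluster_weights))
        for i in range(n)
    ]
    return Cohort(records=records, metadata={"generator": "null", "seed": seed})


# --------------------------------------------------------------------------
# bistable double-well engine

@dataclass
class BistableParams:
    """Double-well landscape, noise, treatment push and score mapping.

    The landscape is ``U(x) = h (x^2 - 1)^2`` with the healthy well at
    x = -1 and the pathological well at x = +1; ``h`` is the barrier
    height. During the treatment phase (duration ``t_treat``) a constant
    bias ``push_d`` is subtracted from the drift; the follow-up phase
    (duration ``t_fup``) relaxes freely. ``caps_healthy``/``caps_sick``
    define the affine map from x in [-1, +1] to a CAPS total, an artifact
    convention (no quantitative score<->state link exists in the clinical
    literature); defaults put the pathological well near the trial's
    baseline mean.
    """

    h: float = 1.0
    noise_sigma: float = 0.2
    push_d: float = 0.0
    t_treat: float = 6.0
    t_fup: float = 12.0
    dt: float = 0.01
    x0: float = 1.0
    caps_healthy: float = 8.0
    caps_sick: float = 44.0
    measurement_noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.h <= 0:
            raise ValueError("barrier height h must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_treat < 0 or self.t_fup < 0:
            raise ValueError("phase durations must be nonnegative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.caps_sick <= self.caps_healthy:
            raise ValueError("caps_sick must exceed caps_healthy")
        if self.dt > DT_STABILITY_FACTOR / self.h:
            raise ValueError(
                f"dt={self.dt} too large for stability: require "
                f"dt <= {DT_STABILITY_FACTOR}/h = {DT_STABILITY_FACTOR / self.h:.4g}")


@dataclass
class Trajectory:
    """One integrated path with phase labels and a terminal well label."""

    time: np.ndarray
    x: np.ndarray
    phase: np.ndarray  # "treatment" | "followup" per step
    terminal: str      # "HEALTHY" | "PATHOLOGICAL" | "UNDECIDED"

    @property
    def x_end_treatment(self) -> float:
        n_treat = int(np.sum(self.phase == "treatment"))
        return float(self.x[n_treat])

    @property
    def x_final(self) -> float:
        return float(self.x[-1])


def _drift(x: np.ndarray | float, h: float, d: float):
    return -4.0 * h * x * (x * x - 1.0) - d


def _terminal_label(x_final: float, margin: float = WELL_MARGIN) -> str:
    if x_final < -margin:
        return "HEALTHY"
    if x_final > margin:
        return "PATHOLOGICAL"
    return "UNDECIDED"


def simulate_bistable_trajectory(params: BistableParams,
                                 rng: Optional[np.random.Generator] = None
                                 ) -> Trajectory:
    """Euler-Maruyama integration of the double-well Langevin dynamics.

    ``dx = [-U'(x) - d * 1(treatment)] dt + sigma dW`` with
    ``U'(x) = 4 h x (x^2 - 1)``. With ``noise_sigma = 0`` the path is
    deterministic (no random numbers are drawn). Raises on a step size
    that violates the documented stability bound.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_treat = int(round(params.t_treat / params.dt))
    n_fup = int(round(params.t_fup / params.dt))
    n = n_treat + n_fup
    x = np.empty(n + 1)
    x[0] = params.x0
    sqdt = math.sqrt(params.dt)
    for k in range(n):
        d = params.push_d if k < n_treat else 0.0
        xi = rng.standard_normal() if params.noise_sigma > 0 else 0.0
        x[k + 1] = (x[k] + _drift(x[k], params.h, d) * params.dt
                    + params.noise_sigma * sqdt * xi)
    phase = np.array(["treatment"] * n_treat + ["followup"] * n_fup)
    time = np.arange(n + 1) * params.dt
    return Trajectory(time=time, x=x, phase=phase,
                      terminal=_terminal_label(x[-1]))


def _integrate_many(params: BistableParams, x0: np.ndarray, d: np.ndarray,
                    rng: Optional[np.random.Generator]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized integration for a population; returns (x at end of
    treatment, x at final time)."""
    params.validate()
    n_treat = int(round(params.t_treat / params.dt))
    n_fup = int(round(params.t_fup / params.dt))
    x = np.array(x0, dtype=float)
    sqdt = math.sqrt(params.dt)
    sigma = params.noise_sigma
    x_post = None
    for k in range(n_treat + n_fup):
        dk = d if k < n_treat else 0.0
        x = x + _drift(x, params.h, dk) * params.dt
        if sigma > 0:
            x = x + sigma * sqdt * rng.standard_normal(x.shape)
        if k == n_treat - 1:
            x_post = x.copy()
    if x_post is None:  # t_treat == 0
        x_post = np.array(x0, dtype=float)
    return x_post, x


def critical_push(params: BistableParams, d_lo: float = 0.0,
                  d_hi: Optional[float] = None, tol: float = 1e-4) -> float:
    """Deterministic critical push d* located by bisection (sigma = 0).

    d* is the smallest constant treatment bias for which the state,
    started at ``params.x0``, ends the treatment + relaxation horizon in
    the healthy well. For long treatment phases d* approaches the
    saddle-node value 8 h / (3 sqrt(3)) at which the pathological well
    disappears.
    """
    def transitions(d: float) -> bool:
        p = BistableParams(**{**asdict(params), "noise_sigma": 0.0, "push_d": d})
        _, x_fin = _integrate_many(p, np.array([p.x0]), d, None)
        return bool(x_fin[0] < 0.0)

    if d_hi is None:
        d_hi = 4.0 * params.h
    if transitions(d_lo):
        raise ValueError("d_lo already induces a transition; no bracket")
    if not transitions(d_hi):
        raise ValueError("d_hi does not induce a transition; widen bracket")
    lo, hi = d_lo, d_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if transitions(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def transition_probability(params: BistableParams, d: float, n_reps: int,
                           seed: int) -> float:
    """Monte-Carlo probability that a push of size ``d`` ends in the
    healthy well (final x < -margin) under the params' noise level."""
    rng = np.random.default_rng(seed)
    x0 = np.full(n_reps, params.x0)
    _, x_final = _integrate_many(params, x0, float(d), rng)
    return float(np.mean(x_final < -WELL_MARGIN))


def map_state_to_caps(x: float, caps_healthy: float, caps_sick: float,
                      noise: float = 0.0) -> int:
    """Affine map of clip(x, -1, +1) from [-1, +1] to the score range,
    plus a noise draw, rounded and clipped to [0, 80]."""
    xc = min(1.0, max(-1.0, float(x)))
    score = caps_healthy + (xc + 1.0) / 2.0 * (caps_sick - caps_healthy) + noise
    return int(min(80, max(0, round(score))))


def generate_bistable_cohort(params: BistableParams, n: int,
                             push_dist: DistSpec, seed: int,
                             cluster_weights: Sequence[float] = DEFAULT_CLUSTER_WEIGHTS
                             ) -> Cohort:
    """Cohort of double-well trajectories with per-subject treatment pushes.

    Each subject's push is drawn from ``push_dist``; PRE/POST/FUP totals
    are the affine-mapped states at baseline, end of treatment and end of
    follow-up, plus measurement noise. Per-subject ground truth (push,
    states, terminal well label) is stored in ``cohort.metadata["bistable"]``.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    pushes = push_dist.sample(rng, n)
    x0 = np.full(n, params.x0)
    x_post, x_final = _integrate_many(params, x0, pushes, rng)
    sd = params.measurement_noise_sd
    noise = rng.normal(0.0, sd, size=(3, n)) if sd > 0 else np.zeros((3, n))
    records = []
    terminals = []
    for i in range(n):
        pre_s = map_state_to_caps(x0[i], params.caps_healthy, params.caps_sick, noise[0, i])
        post_s = map_state_to_caps(x_post[i], params.caps_healthy, params.caps_sick, noise[1, i])
        fup_s = map_state_to_caps(x_final[i], params.caps_healthy, params.caps_sick, noise[2, i])
        pre_s = max(pre_s, 1)  # baseline of 0 would leave ratios undefined
        records.append(ParticipantRecord(
            participant_id=f"B{i + 1:03d}", arm=Arm.ACTIVE,
            pre=_make_scores(pre_s, cluster_weights),
            post=_make_scores(post_s, cluster_weights),
            fup=_make_scores(fup_s, cluster_weights)))
        terminals.append(_terminal_label(float(x_final[i])))
    meta = {
        "generator": "bistable",
        "seed": seed,
        "params": asdict(params),
        "push_dist": push_dist.to_dict(),
        "bistable": {
            "push_d": [float(v) for v in pushes],
            "x_post": [float(v) for v in x_post],
            "x_final": [float(v) for v in x_final],
            "terminal": terminals,
        },
    }
    return Cohort(records=records, metadata=meta)
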