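"""End-to-end pipeline: load or generate a cohort, validate, and run the
threshold, cluster-association and baseline-severity analyses into one
serializable run report.

Every artifact records the resolved configuration and seed; a rerun with
the same config and seed reproduces every number (reports carry no
timestamps, so report JSON files are byte-identical across reruns).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Arm, Cohort, read_cohort, write_cohort, validate_cohort
from .synthetic import (BistableParams, DistSpec, PlantedConfig,
                        generate_bistable_cohort, generate_planted_cohort)
from .elbow import ThresholdElbowModel, default_grid
from .clusters import ClusterAssociationModel, sham_threshold_count
from .baseline import BaselineSeverityModel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "summarize_cohort",
           "CohortSummary", "SEVERITY_BANDS"]

#: baseline severity bands on the 0-80 CAPS-5 total
SEVERITY_BANDS = {
    "subthreshold (<23)": (0, 22),
    "moderate (23-34)": (23, 34),
    "severe (35-50)": (35, 50),
    "extreme (51-80)": (51, 80),
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Exactly one input mode: ``"file"`` (read ``input_path``),
    ``"planted"`` or ``"bistable"`` (generate with the embedded configs).
    """

    mode: str = "planted"
    input_path: Optional[str] = None
    planted: PlantedConfig = field(default_factory=PlantedConfig)
    bistable_params: BistableParams = field(default_factory=BistableParams)
    bistable_n: int = 28
    bistable_push: DistSpec = field(
        default_factory=lambda: DistSpec("uniform", low=0.5, high=2.5))
    arm: str = "ACTIVE"
    grid_step: float = 0.05
    n_min: int = 3
    b_permutation: int = 1000
    b_bootstrap: int = 1000
    method: str = "spearman"
    reference: str = "null_mean"
    statistic: str = "weighted"
    seed: int = 0
    outdir: Optional[str] = None
    run_threshold: bool = True
    run_clusters: bool = True
    run_baseline: bool = True

    def validate(self) -> None:
        if self.mode not in ("file", "planted", "bistable"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "file" and not self.input_path:
            raise ValueError("mode 'file' requires input_path")
        if not (0 < self.grid_step <= 1):
            raise ValueError("grid_step must lie in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted"] = self.planted.to_dict()
        d["bistable_push"] = self.bistable_push.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "planted" in d and isinstance(d["planted"], dict):
            p = dict(d["planted"])
            for k in ("active_improvement_dist", "sham_improvement_dist",
                      "fup_step_dist"):
                if k in p and isinstance(p[k], dict):
                    p[k] = DistSpec.from_dict(p[k])
            if "baseline_range" in p:
                p["baseline_range"] = tuple(p["baseline_range"])
            if "cluster_weights" in p:
                p["cluster_weights"] = tuple(p["cluster_weights"])
            d["planted"] = PlantedConfig(**p)
        if "bistable_params" in d and isinstance(d["bistable_params"], dict):
            d["bistable_params"] = BistableParams(**d["bistable_params"])
        if "bistable_push" in d and isinstance(d["bistable_push"], dict):
            d["bistable_push"] = DistSpec.from_dict(d["bistable_push"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CohortSummary:
    """Arm sizes and baseline descriptives."""

    n_total: int
    n_active: int
    n_sham: int
    baseline_mean: float
    baseline_sd: float
    severity_bands: dict
    n_incomplete: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """n per arm, baseline mean +/- SD and severity-band counts."""
    pre = np.array([r.pre.total for r in cohort.records], dtype=float)
    bands = {}
    for name, (lo, hi) in SEVERITY_BANDS.items():
        bands[name] = int(np.sum((pre >= lo) & (pre <= hi))) if len(pre) else 0
    return CohortSummary(
        n_total=len(cohort),
        n_active=len(cohort.arm(Arm.ACTIVE)),
        n_sham=len(cohort.arm(Arm.SHAM)),
        baseline_mean=float(pre.mean()) if len(pre) else 0.0,
        baseline_sd=float(pre.std(ddof=1)) if len(pre) > 1 else 0.0,
        severity_bands=bands,
        n_incomplete=sum(0 if r.complete() else 1 for r in cohort.records),
    )


@dataclass
class RunReport:
    """Everything one pipeline run computed, serializable to JSON."""

    config: dict
    versions: dict
    cohort_summary: dict
    validation_passed: bool
    validation_rules: list
    elbow: Optional[dict] = None
    associations: Optional[list] = None
    baseline: Optional[dict] = None
    sham_counts: Optional[dict] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _resolve_cohort(config: RunConfig) -> Cohort:
    if config.mode == "file":
        return read_cohort(config.input_path)
    if config.mode == "planted":
        cfg = dataclasses.replace(config.planted, seed=config.seed)
        return generate_planted_cohort(cfg)
    params = dataclasses.replace(config.bistable_params, seed=config.seed)
    return generate_bistable_cohort(params, config.bistable_n,
                                    config.bistable_push, seed=config.seed)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run load/generate -> validate -> threshold -> associations ->
    baseline severity, writing artifacts to ``config.outdir`` if set."""
    config.validate()
    logger.info("[load] mode=%s seed=%d", config.mode, config.seed)
    cohort = _resolve_cohort(config)

    logger.info("[validate] %d records", len(cohort))
    report = validate_cohort(cohort)
    if report.errors:
        raise ValueError(f"[validate] cohort has {len(report.errors)} "
                         f"error-grade violations: {sorted(report.rules())}")

    summary = summarize_cohort(cohort)
    grid = default_grid(config.grid_step)
    # artifact location is not part of the analysis configuration: keeping
    # it out makes reports from identical configs byte-identical
    cfg_dict = config.to_dict()
    cfg_dict["outdir"] = None
    out = RunReport(
        config=cfg_dict,
        versions=_versions(),
        cohort_summary=summary.to_dict(),
        validation_passed=report.passed,
        validation_rules=sorted(report.rules()),
    )

    elbow_res = None
    if config.run_threshold:
        logger.info("[threshold] B=%d", config.b_permutation)
        model = ThresholdElbowModel(cohort, arm=config.arm, grid=grid,
                                    n_min=config.n_min)
        elbow_res = model.fit(b=config.b_permutation, seed=config.seed,
                              reference=config.reference,
                              statistic=config.statistic)
        r = elbow_res.result
        out.elbow = {
            "t_star": r.t_star, "improvement_pct": r.improvement_pct,
            "d_obs": r.d_obs, "p_value": r.p_value,
            "n_at_t_star": r.n_at_t_star, "b": r.b,
            "reference": r.reference, "statistic": r.statistic,
            "seed": config.seed,
        }

    assoc_res = None
    if config.run_clusters:
        logger.info("[clusters] method=%s B=%d", config.method,
                    config.b_bootstrap)
        cmodel = ClusterAssociationModel(cohort, arm=config.arm)
        assoc_res = cmodel.fit(method=config.method, b=config.b_bootstrap,
                               seed=config.seed)
        out.associations = assoc_res.to_frame().to_dict(orient="records")
        if summary.n_sham:
            sc = sham_threshold_count(cohort)
            out.sham_counts = asdict(sc)

    base_res = None
    if config.run_baseline:
        logger.info("[baseline] arm=%s", config.arm)
        bmodel = BaselineSeverityModel(cohort, arm=config.arm)
        base_res = bmodel.fit()
        out.baseline = {
            "correlations": {
                f"{tp}_{method}": res.to_dict()
                for (tp, method), res in base_res.correlations.items()
            },
            "n_improved": base_res.split.n_improved,
            "n_worsened": base_res.split.n_worsened,
            "n_ties": base_res.split.n_ties,
            "mann_whitney": (None if base_res.mann_whitney is None
                             else asdict(base_res.mann_whitney)),
        }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, outdir / "cohort.csv")
        (outdir / "report.json").write_text(out.to_json())
        if elbow_res is not None:
            curve = elbow_res.curve
            pd.DataFrame({"t": curve.grid, "f": curve.f, "n": curve.n,
                          "null_mean": elbow_res.null.mean_curve,
                          "d": elbow_res.result.d_curve}
                         ).to_csv(outdir / "responder_curve.csv", index=False)
        if assoc_res is not None:
            assoc_res.to_frame().to_csv(outdir / "associations.csv",
                                        index=False)
        logger.info("[write] artifacts in %s", outdir)

    return out


def _versions() -> dict:
    import scipy

    return {
        "capselbow": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
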