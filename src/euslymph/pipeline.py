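"""End-to-end orchestration: simulate -> agree -> derive -> evaluate -> report.

A single seeded run reproduces, on synthetic or supplied data, every table
of the criteria-development workflow: the per-feature agreement table, the
class-comparison table, ROC-derived size cutoffs, both criteria
definitions, the accuracy table at the >=2 and all-items operating points,
ROC points and the paired DeLong comparison.  Every artifact embeds a run
record (config + seed + package version) and the whole report is
byte-deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .agreement import consolidate_majority, feature_agreement
from .criteria import (
    build_feature_frame,
    group_comparison,
    new_criteria,
    old_criteria,
    score_table,
    select_features,
    youden_cutoff,
)
from .errors import ConfigError, EusLymphError, PipelineStageError
from .evaluation import delong_compare, diagnostic_metrics, roc_from_scores
from .io import SCHEMA_VERSION, read_lesion_table, read_rating_table, write_json
from .model import RatingTable
from .simulate import CohortConfig, RaterNoiseConfig, generate_cohort, generate_ratings

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration.

    Either both input CSV paths are given, or the simulation configs are
    used.  All stage randomness (cohort, panel, bootstrap) is derived
    deterministically from ``seed``.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    noise: RaterNoiseConfig = field(default_factory=RaterNoiseConfig)
    lesions_path: str | None = None
    ratings_path: str | None = None
    bootstrap_b: int = 2000
    kappa_threshold: float = 0.4
    grid_mm: float = 5.0
    min_votes: int = 3
    strict: bool = True
    ci_level: float = 0.95
    new_threshold: int = 2
    old_threshold: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.lesions_path is None) != (self.ratings_path is None):
            raise ConfigError(
                "provide both lesions_path and ratings_path, or neither"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict = {}
        if "cohort" in d:
            kwargs["cohort"] = CohortConfig(**d.pop("cohort"))
        if "noise" in d:
            kwargs["noise"] = RaterNoiseConfig(**d.pop("noise"))
        kwargs.update(d.pop("pipeline", {}))
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(3)
    names = ("cohort", "raters", "bootstrap")
    return {n: int(s) & 0x7FFFFFFF for n, s in zip(names, state)}


def _config_record(config: PipelineConfig) -> dict:
    rec = dataclasses.asdict(config)

    def clean(obj):
        if isinstance(obj, dict):
            return {str(k): clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return clean(rec)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the whole workflow; returns (and optionally writes) the report."""
    seeds = _stage_seeds(config.seed)

    # --- stage: inputs -----------------------------------------------------
    stage = "simulate" if config.lesions_path is None else "load"
    try:
        if config.lesions_path is None:
            cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["cohort"])
            noise_cfg = dataclasses.replace(config.noise, seed=seeds["raters"])
            lesions, truth = generate_cohort(cohort_cfg)
            ratings: RatingTable = generate_ratings(truth, noise_cfg)
        else:
            lesions = read_lesion_table(config.lesions_path)
            ratings = read_rating_table(config.ratings_path)
    except EusLymphError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # --- stage: agree ------------------------------------------------------
    try:
        agreements = feature_agreement(
            ratings, B=config.bootstrap_b, level=config.ci_level,
            seed=seeds["bootstrap"],
        )
        consensus = consolidate_majority(ratings, min_votes=config.min_votes)
    except EusLymphError as exc:
        raise PipelineStageError("agree", str(exc)) from exc

    frame = build_feature_frame(lesions, consensus)
    labels = frame["diagnosis"].to_numpy()

    # --- stage: derive -----------------------------------------------------
    try:
        long_cut = youden_cutoff(
            frame["long_axis_mm"], labels, axis="long", grid_mm=config.grid_mm
        )
        short_cut = youden_cutoff(
            frame["short_axis_mm"], labels, axis="short", grid_mm=config.grid_mm
        )
        selected = select_features(agreements, config.kappa_threshold)
        new_def = new_criteria(
            long_cutoff_mm=long_cut.rounded_cutoff_mm,
            short_cutoff_mm=short_cut.rounded_cutoff_mm,
            strict=config.strict,
            extra_features=[f for f in selected if f != "shape"],
        )
        old_def = old_criteria(strict=config.strict)
    except EusLymphError as exc:
        raise PipelineStageError("derive", str(exc)) from exc

    # --- stage: evaluate ---------------------------------------------------
    try:
        new_scores = score_table(frame, new_def)["score"].to_numpy()
        old_scores = score_table(frame, old_def)["score"].to_numpy()
        comparison = group_comparison(frame)
        roc_new = roc_from_scores(new_scores, labels, level=config.ci_level)
        roc_old = roc_from_scores(old_scores, labels, level=config.ci_level)
        paired = delong_compare(new_scores, old_scores, labels)
        performance = {
            f"new_ge{config.new_threshold}": diagnostic_metrics(
                new_scores, labels, config.new_threshold, level=config.ci_level
            ),
            f"new_ge{new_def.n_items}": diagnostic_metrics(
                new_scores, labels, new_def.n_items, level=config.ci_level
            ),
            f"old_ge{config.old_threshold}": diagnostic_metrics(
                old_scores, labels, config.old_threshold, level=config.ci_level
            ),
            f"old_ge{config.old_threshold + 1}": diagnostic_metrics(
                old_scores, labels, config.old_threshold + 1, level=config.ci_level
            ),
        }
    except EusLymphError as exc:
        raise PipelineStageError("evaluate", str(exc)) from exc

    report = _build_report(
        config, seeds, agreements, long_cut, short_cut, new_def, old_def,
        comparison, performance, roc_new, roc_old, paired,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_lesion_table, write_rating_table

        write_lesion_table(lesions, outdir / "lesions.csv")
        write_rating_table(ratings, outdir / "ratings.csv")
        write_json(report, outdir / "report.json")
    return report


def _perf_dict(perf) -> dict:
    return {
        "tp": perf.tp,
        "fp": perf.fp,
        "tn": perf.tn,
        "fn": perf.fn,
        "sensitivity": perf.sensitivity,
        "specificity": perf.specificity,
        "accuracy": perf.accuracy,
        "ppv": perf.ppv,
        "npv": perf.npv,
        "ci": {k: list(v) if v else None for k, v in perf.ci.items()},
        "undefined": list(perf.undefined),
    }


def _roc_dict(roc) -> dict:
    thr = ["inf" if not np.isfinite(t) and t > 0 else
           "-inf" if not np.isfinite(t) else float(t)
           for t in roc.thresholds]
    return {
        "thresholds": thr,
        "sensitivity": [float(x) for x in roc.sensitivity],
        "specificity": [float(x) for x in roc.specificity],
        "auc": roc.auc,
        "auc_se": roc.auc_se,
        "auc_ci": list(roc.auc_ci),
    }


def _build_report(
    config, seeds, agreements, long_cut, short_cut, new_def, old_def,
    comparison, performance, roc_new, roc_old, paired,
) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "run_record": {
            "package": "euslymph",
            "version": _pkg_version(),
            "seed": config.seed,
            "stage_seeds": seeds,
            "config": _config_record(config),
        },
        "agreement": [
            {
                "feature": a.feature,
                "kappa": a.kappa,
                "ci": [a.ci_low, a.ci_high],
                "label": a.landis_label,
                "n_lesions_used": a.n_lesions_used,
                "per_category": a.per_category,
            }
            for a in agreements
        ],
        "cutoffs": {
            c.axis: {
                "youden_cutoff_mm": c.youden_cutoff_mm,
                "rounded_cutoff_mm": c.rounded_cutoff_mm,
                "youden_j": c.youden_j,
                "sens_at_youden": c.sens_at_youden,
                "spec_at_youden": c.spec_at_youden,
                "sens_at_rounded": c.sens_at_rounded,
                "spec_at_rounded": c.spec_at_rounded,
            }
            for c in (long_cut, short_cut)
        },
        "criteria": {"new": new_def.to_dict(), "old": old_def.to_dict()},
        "group_comparison": comparison,
        "performance": {k: _perf_dict(v) for k, v in performance.items()},
        "roc": {"new": _roc_dict(roc_new), "old": _roc_dict(roc_old)},
        "delong": {
            "auc_new": paired.auc_a,
            "auc_old": paired.auc_b,
            "delta": paired.delta,
            "variance": paired.variance,
            "z": paired.z,
            "p": paired.p,
            "degenerate": paired.degenerate,
        },
    }


def _pkg_version() -> str:
    from . import __version__

    return __version__


def validate_report(report: dict) -> None:
    """Assert the report's structural and arithmetic identities.

    Checks schema keys, confusion-margin consistency and the Bayes
    identity linking PPV to sensitivity/specificity/prevalence.
    Raises ``AssertionError`` on the first violation.
    """
    for key in (
        "schema_version", "run_record", "agreement", "cutoffs",
        "criteria", "group_comparison", "performance", "roc", "delong",
    ):
        assert key in report, f"report missing key {key!r}"
    n_pos = n_neg = None
    for name, perf in report["performance"].items():
        tp, fp, tn, fn = perf["tp"], perf["fp"], perf["tn"], perf["fn"]
        if n_pos is None:
            n_pos, n_neg = tp + fn, tn + fp
        assert tp + fn == n_pos, f"{name}: malignant margin changed"
        assert tn + fp == n_neg, f"{name}: benign margin changed"
        total = tp + fp + tn + fn
        assert abs(perf["accuracy"] - (tp + tn) / total) < 1e-12
        if perf["ppv"] is not None and perf["sensitivity"] is not None:
            pi = n_pos / total
            sens, spec = perf["sensitivity"], perf["specificity"]
            denom = sens * pi + (1 - spec) * (1 - pi)
            if denom > 0:
                assert abs(perf["ppv"] - sens * pi / denom) < 1e-12, (
                    f"{name}: Bayes identity violated"
                )
    for arm in ("new", "old"):
        roc = report["roc"][arm]
        sens = np.asarray(roc["sensitivity"])
        spec = np.asarray(roc["specificity"])
        assert (np.diff(sens) >= -1e-12).all(), f"{arm}: sens not monotone"
        assert (np.diff(spec) <= 1e-12).all(), f"{arm}: spec not monotone"
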