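"""File formats, run configuration and the end-to-end pipeline.

Cohort CSVs carry one measured sample per row with explicit units in the
column names (study_id, patient_id, sample_id, thickness_mm, pressure_kpa);
summary studies live in JSON as {label, mean_mm, sd_mm, n}.  The pipeline
ties the stages together: build/load the response surface, fit the
hierarchical model, produce diagnostics, the predictive summary and the
study-level pressure corrections, every artifact stamped with the seed and
a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .constitutive import ResponseSurface, build_response_surface
from .hierarchical import (
    PriorSpec,
    ThicknessSample,
    build_model,
    diagnostics,
    posterior_summary,
    sample_posterior,
)
from .predictive import (
    fit_lognormal_approx,
    posterior_predictive,
    shift_metrics,
    tail_probability,
    undeform_study,
)
from .summary_likelihood import SummaryStatStudy

__all__ = [
    "COHORT_COLUMNS",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "read_summaries",
    "write_summaries",
    "run_pipeline",
]

log = logging.getLogger("aawt")

COHORT_COLUMNS = ("study_id", "patient_id", "sample_id", "thickness_mm", "pressure_kpa")


def read_cohort(path) -> list[ThicknessSample]:
    """Read and validate a cohort CSV; offending rows are named on error."""
    df = pd.read_csv(
        path,
        dtype={"study_id": str, "patient_id": str, "sample_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    errors = []
    for i, row in df.iterrows():
        if not row["thickness_mm"] > 0:
            errors.append(f"row {i + 2}: non-positive thickness_mm {row['thickness_mm']}")
        if row["pressure_kpa"] < 0:
            errors.append(f"row {i + 2}: negative pressure_kpa {row['pressure_kpa']}")
    keys = list(zip(df["study_id"], df["patient_id"], df["sample_id"]))
    seen: set = set()
    for i, key in enumerate(keys):
        if key in seen:
            errors.append(f"row {i + 2}: duplicate key {key}")
        seen.add(key)
    if errors:
        raise ValueError(f"{path}: invalid cohort data:\n  " + "\n  ".join(errors))
    return [
        ThicknessSample(
            study_id=row["study_id"],
            patient_id=row["patient_id"],
            sample_id=row["sample_id"],
            t=float(row["thickness_mm"]),
            p=float(row["pressure_kpa"]),
        )
        for _, row in df.iterrows()
    ]


def write_cohort(samples: Sequence[ThicknessSample], path) -> None:
    pd.DataFrame(
        {
            "study_id": [s.study_id for s in samples],
            "patient_id": [s.patient_id for s in samples],
            "sample_id": [s.sample_id for s in samples],
            "thickness_mm": [s.t for s in samples],
            "pressure_kpa": [s.p for s in samples],
        }
    ).to_csv(path, index=False, float_format="%.17g")  # exact float round trip


def read_summaries(path) -> list[SummaryStatStudy]:
    """Summary-statistics studies from JSON: [{label, mean_mm, sd_mm, n}]."""
    with open(path) as fh:
        data = json.load(fh)
    return [
        SummaryStatStudy(M=d["mean_mm"], S=d["sd_mm"], N=d["n"], label=d.get("label", ""))
        for d in data
    ]


def write_summaries(summaries: Sequence[SummaryStatStudy], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {"label": s.label, "mean_mm": s.M, "sd_mm": s.S, "n": s.N}
                for s in summaries
            ],
            fh,
            indent=2,
        )


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    data: str | None = None
    summaries: str | None = None
    surface: str | None = None  # load if the file exists, else build and save
    out_dir: str = "aawt-out"
    seed: int = 0
    chains: int = 4
    draws: int = 2000
    warmup: int = 500
    paper_scale: bool = False  # 20 chains x 10000 draws
    n_predictive: int = 100_000
    surface_spec: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("data", "summaries", "surface"):
            p = getattr(cfg, name)
            if name != "surface" and p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name}={p} does not resolve")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def prior_spec(self) -> PriorSpec:
        kw = {k: tuple(v) for k, v in self.priors.items()}
        return PriorSpec(**kw)


def _ensure_surface(cfg: RunConfig) -> ResponseSurface:
    if cfg.surface and Path(cfg.surface).exists():
        log.info("loading response surface from %s", cfg.surface)
        return ResponseSurface.load(cfg.surface)
    t0 = time.time()
    surf = build_response_surface(**cfg.surface_spec)
    log.info(
        "response surface built in %.1f s (max emulator error %.2e)",
        time.time() - t0,
        surf.metadata["achieved_max_error"],
    )
    if cfg.surface:
        surf.save(cfg.surface)
    return surf


def run_pipeline(config: RunConfig) -> dict:
    """Run surface building, inference, prediction and correction.

    Returns the output bundle as a dict and writes CSV/JSON artifacts to the
    configured output directory.  On a stage failure, artifacts of completed
    stages remain on disk and the failing stage is named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    bundle: dict = {"stamp": stamp}
    stage = "read-inputs"
    try:
        samples = read_cohort(config.data) if config.data else []
        summaries = read_summaries(config.summaries) if config.summaries else []

        stage = "build-surface"
        surface = _ensure_surface(config)

        stage = "fit"
        model = build_model(samples, summaries, surface, priors=config.prior_spec())
        chains, draws = (20, 10_000) if config.paper_scale else (config.chains, config.draws)
        t0 = time.time()
        post = sample_posterior(
            model, chains=chains, draws=draws, warmup=config.warmup, seed=config.seed
        )
        log.info("sampling done in %.1f s", time.time() - t0)
        post.to_frame().to_csv(out / "posterior_draws.csv", index=False)

        stage = "diagnostics"
        rep = diagnostics(post)
        summary = {
            name: {
                "median": posterior_summary(post, name)[0],
                "ci95": list(posterior_summary(post, name)[1]),
                "rhat": rep["rhat"].get(name),
                "ess": rep["ess"].get(name),
            }
            for name in post.param_names
        }
        bundle["posterior"] = summary
        bundle["diagnostics"] = {
            "max_rhat": rep["max_rhat"],
            "min_ess": rep["min_ess"],
            "pairwise": rep.get("pairwise", {}),
            "divergences": post.divergences,
        }

        stage = "predict"
        pred = posterior_predictive(post, config.n_predictive, seed=config.seed)
        mu_fit, sigma_fit = fit_lognormal_approx(pred)
        tails = {
            f"{t1:.1f}": tail_probability(mu_fit, sigma_fit, t1)
            for t1 in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
        }
        bundle["predictive"] = {
            **pred.summary(),
            "lognormal_mu": mu_fit,
            "lognormal_sigma": sigma_fit,
            "tail_probability_pct": tails,
        }
        pd.DataFrame({"thickness_mm": pred.draws}).to_csv(
            out / "predictive_draws.csv", index=False
        )

        stage = "correct"
        if samples:
            by_study: dict[str, list[ThicknessSample]] = {}
            for s in samples:
                by_study.setdefault(s.study_id, []).append(s)
            records = [
                undeform_study(group, post, surface) for group in by_study.values()
            ]
            bundle["corrections"] = [r.__dict__ for r in records]
            if len(records) >= 2:
                bundle["shift_metrics"] = shift_metrics(records)
            pd.DataFrame([r.__dict__ for r in records]).to_csv(
                out / "corrections.csv", index=False
            )

        with open(out / "summary.json", "w") as fh:
            json.dump(bundle, fh, indent=2, default=float)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
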