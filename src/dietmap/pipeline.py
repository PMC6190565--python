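"""End-to-end orchestration: simulate/load -> map -> augment -> aggregate -> test.

A single YAML config (one top-level seed, thresholds, paths or a request to
simulate) drives a full run; every artifact lands in one run directory and
the resolved config is echoed there, so re-running it reproduces all CSV
outputs byte-identically.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import io
from .augment import apply_mapping
from .coverage import daily_coverage_ratios, group_noncovered_report, pooled_coverage_ratios
from .inference import day_of_week_tests, ratio_density, test_results_frame
from .matching import MatchConfig, build_mapping_table
from .simulate import SynthConfig, generate_catalogue, generate_diary, generate_sfq_definition
from .types import MappingStatus, ValidationError

log = logging.getLogger("dietmap")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": True,
    "synth": {},          # SynthConfig field overrides
    "paths": {},          # diary / sfq / catalogue / overrides when simulate=false
    "match": {"fuzzy_threshold": 0.85, "review_band": [0.85, 0.95], "fuzzy_enabled": True},
    "test": {"alpha": 0.01, "n_perm": 9999, "mode": "permutation"},
    "n_days": 4,
    "plots": True,
}


def load_config(path_or_dict) -> dict[str, Any]:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def run_pipeline(config, out_dir) -> Path:
    """Execute every stage and write all artifacts under ``out_dir``."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: dict[str, Any], out: Path) -> Path:
    seed = int(cfg["seed"])
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    # --- stage 1: inputs -------------------------------------------------
    if cfg["simulate"]:
        synth = SynthConfig(seed=seed, **cfg["synth"])
        catalogue, truth = generate_catalogue(synth)
        diary = generate_diary(synth, catalogue, truth)
        sfq = generate_sfq_definition(synth)
        n_days = synth.n_days
        io.write_catalogue(catalogue, out / "catalogue.csv")
        io.write_food_diary(diary, out / "diary.csv")
        pd.DataFrame(
            {
                "food_code": list(truth.code_to_sfq),
                "true_sfq_group": [v or "" for v in truth.code_to_sfq.values()],
            }
        ).to_csv(out / "truth.csv", index=False)
        log.info("simulated %d catalogue codes, %d diary rows", len(catalogue), len(diary))
        overrides = None
    else:
        paths = cfg["paths"]
        for key in ("diary", "sfq", "catalogue"):
            if not paths.get(key):
                raise ValidationError(f"config paths.{key} is required when simulate=false")
        diary = io.read_food_diary(paths["diary"], schema=paths.get("diary_schema"))
        catalogue = io.read_catalogue(paths["catalogue"])
        sfq = io.read_sfq_definition(paths["sfq"])
        overrides = (
            io.read_mapping_table(paths["overrides"]) if paths.get("overrides") else None
        )
        n_days = int(cfg["n_days"])
        log.info("read %d diary rows, %d catalogue codes", len(diary), len(catalogue))

    # --- stage 2: mapping ------------------------------------------------
    mcfg = MatchConfig(
        fuzzy_threshold=float(cfg["match"]["fuzzy_threshold"]),
        review_band=tuple(cfg["match"]["review_band"]),
        fuzzy_enabled=bool(cfg["match"].get("fuzzy_enabled", True)),
    )
    mapping = build_mapping_table(catalogue, sfq, mcfg, manual_overrides=overrides)
    io.write_mapping_table(mapping, out / "mapping.csv")
    by_step: dict[str, int] = {}
    for m in mapping:
        by_step[m.match_step.value] = by_step.get(m.match_step.value, 0) + 1
    log.info(
        "mapped %d codes (%s); %d flagged for review",
        len(mapping),
        ", ".join(f"{k}={v}" for k, v in sorted(by_step.items())),
        sum(m.needs_review for m in mapping),
    )

    # --- stage 3: augmentation ------------------------------------------
    augmented = apply_mapping(diary, mapping)
    io.write_augmented(augmented, out / "augmented.csv")

    # --- stage 4: coverage aggregation ----------------------------------
    coverage = daily_coverage_ratios(augmented)
    io.write_coverage(coverage, out / "coverage.csv")
    excluded = int(coverage["amount_ratio_missing"].sum())
    if excluded:
        log.info("%d zero-intake subject-days excluded from amount-ratio aggregation", excluded)
    report = group_noncovered_report(augmented, n_days=n_days)
    report.to_csv(out / "group_report.csv", index=False)
    pooled_f, pooled_a = pooled_coverage_ratios(augmented)
    log.info(
        "mean non-covered ratios: freq %.3f (pooled %.3f), amount %.3f (pooled %.3f)",
        coverage["freq_ratio"].mean(), pooled_f,
        coverage["amount_ratio"].mean(), pooled_a,
    )

    # --- stage 5: densities and day-of-week tests -----------------------
    tcfg = cfg["test"]
    reports = []
    for metric in ("freq_ratio", "amount_ratio"):
        values = coverage[metric].dropna().to_numpy()
        if len(values) >= 2:
            grid, dens = ratio_density(values)
            pd.DataFrame({"x": grid, "density": dens}).to_csv(
                out / f"density_{metric}.csv", index=False
            )
        if len(set(coverage["weekday"])) >= 2:
            reports.append(
                day_of_week_tests(
                    coverage,
                    metric=metric,
                    alpha=float(tcfg["alpha"]),
                    mode=tcfg["mode"],
                    n_perm=int(tcfg["n_perm"]),
                    seed=seed,
                )
            )
    if reports:
        test_results_frame(reports).to_csv(out / "test_results.csv", index=False)
        for rep in reports:
            log.info("%s: weekdays flagged at alpha=%s: %s", rep.metric, rep.alpha, rep.flagged)

    if cfg.get("plots", True):
        from .reporting import plot_ratio_distributions, plot_weekday_densities

        plot_ratio_distributions(coverage, out / "ratio_distributions.png")
        plot_weekday_densities(coverage, out / "weekday_densities.png")

    log.info("run complete: %s", out)
    return out
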