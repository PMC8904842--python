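"""Study orchestration: groups × animals, summaries and structured reports.

A :class:`StudyConfig` describes the experimental groups (e.g. a normoxic
control and short/long-term intermittent-hypoxia cohorts), the per-stage
generator or input parameters, and the RNG seed.  :func:`run_study` executes
the tensile, residual-strain, dose-response and histology stages per animal,
aggregates means ± SEM per group, and computes relative differences between
groups.  Hypothesis testing beyond descriptive summaries is deliberately
delegated to standard statistical software.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import residual, synthetic, vasoreactivity
from .histology import deconvolve_stains, fiber_fractions
from .tensile import TensileConfig, TensileTest

__all__ = [
    "StudyConfig",
    "GroupSummary",
    "default_synthetic_study",
    "relative_difference",
    "group_summary",
    "run_study",
]

REPORT_SCHEMA_VERSION = "1"

#: Reference group-mean parameter sets for the three exposure groups
#: (normobaric normoxia NN; short- and long-term intermittent hypobaric
#: hypoxia STH/LTH), used as defaults for synthetic cohort generation.
REFERENCE_GROUP_MEANS = {
    "NN": {
        "tensile": {"E1_true": 13.88, "E2_true": 3102.0, "lambda_a": 2.21, "lambda_b": 3.01, "lambda_r_true": 3.80},
        "ring": {"alpha_true": 100.0},
        "ccrc": {"log_ec50": -6.5, "top": 100.0},
        "histology": {"elastin_fraction": 0.2566, "collagen_fraction": 0.1653},
    },
    "STH": {
        "tensile": {"E1_true": 16.78, "E2_true": 4913.0, "lambda_a": 2.66, "lambda_b": 3.46, "lambda_r_true": 4.46},
        "ring": {"alpha_true": 60.0},
        "ccrc": {"log_ec50": -6.8, "top": 110.0},
        "histology": {"elastin_fraction": 0.4069, "collagen_fraction": 0.2139},
    },
    "LTH": {
        "tensile": {"E1_true": 8.01, "E2_true": 1711.0, "lambda_a": 2.69, "lambda_b": 3.49, "lambda_r_true": 4.40},
        "ring": {"alpha_true": 55.0},
        "ccrc": {"log_ec50": -6.6, "top": 120.0},
        "histology": {"elastin_fraction": 0.2495, "collagen_fraction": 0.1324},
    },
}


@dataclass
class GroupSummary:
    """Mean ± SEM (SD/√n) of one parameter within one group."""

    mean: float
    sem: float
    n: int
    n1_flag: bool = False


@dataclass
class StudyConfig:
    """Declarative study layout for :func:`run_study`.

    ``groups`` maps group name -> {"n_animals": int, "tensile": {...},
    "ring": {...}, "ccrc": {...}, "histology": {...}} parameter blocks
    (generator ground-truth means in synthetic mode).  ``stages`` toggles
    stages on/off.  ``noise`` holds the measurement-noise settings and
    ``biological_cv`` the between-animal coefficient of variation applied to
    the tensile moduli.
    """

    groups: dict
    seed: int = 0
    synthetic: bool = True
    stages: dict = field(default_factory=lambda: {"tensile": True, "ring": True, "ccrc": True, "histology": True})
    biological_cv: float = 0.05
    noise: dict = field(default_factory=lambda: {"tensile_relative_sd": 0.05, "ring_jitter_um": 20.0, "ccrc_sd": 3.0})
    tensile_config: TensileConfig = field(default_factory=TensileConfig)
    output_dir: Optional[str] = None

    def validate(self):
        missing = []
        if not self.groups:
            missing.append("groups")
        for name, block in (self.groups or {}).items():
            if "n_animals" not in block:
                missing.append(f"groups.{name}.n_animals")
            for stage, on in self.stages.items():
                if on and stage not in block:
                    missing.append(f"groups.{name}.{stage}")
        if len(set(self.groups)) != len(self.groups):
            missing.append("groups (duplicate names)")
        if missing:
            raise ValueError("invalid study config; missing blocks: " + ", ".join(missing))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        payload = yaml.safe_load(Path(path).read_text())
        tc = TensileConfig(**payload.pop("tensile_config", {}))
        return cls(tensile_config=tc, **payload)


def default_synthetic_study(
    n_animals: int = 6, seed: int = 0, histology: bool = True
) -> StudyConfig:
    """Three-group synthetic study around the reference group means."""
    groups = {}
    for name, blocks in REFERENCE_GROUP_MEANS.items():
        groups[name] = {"n_animals": n_animals}
        for stage, params in blocks.items():
            groups[name][stage] = dict(params)
    cfg = StudyConfig(groups=groups, seed=seed)
    cfg.stages["histology"] = histology
    return cfg


def relative_difference(
    reference_mean: float, comparison_mean: float, round_to: Optional[int] = None
) -> float:
    """Signed percent change 100·(comparison − reference)/reference.

    ``round_to`` applies decimal rounding for report text (0 = nearest
    integer); by default full precision is returned.
    """
    if reference_mean == 0:
        raise ValueError("reference mean must be non-zero")
    value = 100.0 * (comparison_mean - reference_mean) / reference_mean
    if round_to is not None:
        value = round(value, round_to) if round_to > 0 else float(round(value))
    return value


def group_summary(values_per_group: dict) -> dict:
    """Per-group :class:`GroupSummary` of one parameter.

    A single-animal group gets SEM 0 with ``n1_flag`` set (keeps report
    tables rectangular); an empty group is an error.
    """
    out = {}
    for name, values in values_per_group.items():
        vals = np.asarray(list(values), dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"empty group: {name}")
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out[name] = GroupSummary(mean=float(vals.mean()), sem=sem, n=n, n1_flag=(n == 1))
    return out


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _run_tensile_stage(cfg: StudyConfig, rng) -> dict:
    per_group: dict = {}
    for gname, block in cfg.groups.items():
        base = synthetic.TensileGroundTruth(
            noise_sd=cfg.noise.get("tensile_relative_sd", 0.05),
            noise_mode="relative",
            **block["tensile"],
        )
        if base.noise_sd == 0:
            base = dataclasses.replace(base, noise_mode="additive")
        records, _ = synthetic.gen_tensile_cohort(
            base, block["n_animals"], biological_cv=cfg.biological_cv, seed=_spawn_seed(rng)
        )
        rows = []
        for rec in records:
            res = TensileTest(rec, cfg.tensile_config).fit()
            rows.append(res.as_dict())
        per_group[gname] = rows
    return per_group


def _run_ring_stage(cfg: StudyConfig, rng) -> dict:
    per_group: dict = {}
    jitter = cfg.noise.get("ring_jitter_um", 0.0)
    for gname, block in cfg.groups.items():
        alphas = []
        for _ in range(block["n_animals"]):
            ph = synthetic.RingPhantom(
                jitter_sd=jitter, seed=_spawn_seed(rng), **block["ring"]
            )
            contour, _ = synthetic.gen_ring_contour(ph)
            alphas.append(residual.opening_angle(contour).alpha)
        per_group[gname] = alphas
    return per_group


def _run_ccrc_stage(cfg: StudyConfig, rng) -> dict:
    per_group: dict = {}
    sd = cfg.noise.get("ccrc_sd", 0.0)
    for gname, block in cfg.groups.items():
        fits = []
        for _ in range(block["n_animals"]):
            gt = synthetic.CCRCGroundTruth(
                noise_sd=sd, seed=_spawn_seed(rng), **block["ccrc"]
            )
            data = synthetic.gen_ccrc(gt)
            fits.append(vasoreactivity.fit_ccrc(data.doses, data.response))
        per_group[gname] = fits
    return per_group


def _run_histology_stage(cfg: StudyConfig, rng) -> dict:
    per_group: dict = {}
    for gname, block in cfg.groups.items():
        rows = []
        for _ in range(block["n_animals"]):
            ph = synthetic.HistologyPhantom(
                inner_diameter=220.0,
                outer_diameter=340.0,
                pixel_size=0.5,
                n_nuclei=0,
                seed=_spawn_seed(rng),
                **block["histology"],
            )
            image, truth = synthetic.gen_histology_image(ph)
            conc = deconvolve_stains(image.pixels)
            fracs = fiber_fractions(conc, image.roi_mask())
            rows.append({"elastin_pct": fracs.elastin_pct, "collagen_pct": fracs.collagen_pct})
        per_group[gname] = rows
    return per_group


def _summaries_to_jsonable(summaries: dict) -> dict:
    return {
        param: {g: dataclasses.asdict(s) for g, s in groups.items()}
        for param, groups in summaries.items()
    }


def run_study(config: StudyConfig) -> dict:
    """Execute all enabled stages and return the structured study report.

    In synthetic mode a full cohort is generated from the configured group
    means first; per-animal analyses then recover the parameters, which are
    aggregated as mean ± SEM per group.  The report payload is fully
    deterministic for a fixed seed (no timestamps).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if not config.synthetic:
        raise NotImplementedError(
            "file-based studies are driven through the per-stage CLI commands; "
            "run_study currently orchestrates synthetic cohorts"
        )
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "groups": {g: {"n_animals": b["n_animals"]} for g, b in config.groups.items()},
        "stages": {},
        "tables": {},
        "relative_differences": [],
        "errors": [],
    }
    summaries: dict = {}

    if config.stages.get("tensile"):
        tensile = _run_tensile_stage(config, rng)
        report["stages"]["tensile"] = tensile
        for param in ("E1_kPa", "E2_kPa", "lambda_t", "sigma_t_kPa", "lambda_r", "sigma_r_kPa", "Et_uJ_mm3", "Er_uJ_mm3"):
            summaries[param] = group_summary(
                {g: [row[param] for row in rows] for g, rows in tensile.items()}
            )
    if config.stages.get("ring"):
        ring = _run_ring_stage(config, rng)
        report["stages"]["ring"] = ring
        summaries["opening_angle_deg"] = group_summary(ring)
    if config.stages.get("ccrc"):
        ccrc = _run_ccrc_stage(config, rng)
        report["stages"]["ccrc"] = {
            g: [dataclasses.asdict(f) for f in fits] for g, fits in ccrc.items()
        }
        summaries["pd2"] = group_summary(
            {g: [f.pd2 for f in fits if f.converged] for g, fits in ccrc.items()}
        )
        summaries["emax"] = group_summary(
            {g: [f.emax for f in fits if f.converged] for g, fits in ccrc.items()}
        )
    if config.stages.get("histology"):
        histo = _run_histology_stage(config, rng)
        report["stages"]["histology"] = histo
        for param in ("elastin_pct", "collagen_pct"):
            summaries[param] = group_summary(
                {g: [row[param] for row in rows] for g, rows in histo.items()}
            )
        if {"NN", "STH", "LTH"} <= set(config.groups):
            e = summaries["elastin_pct"]
            report["relative_differences"] = [
                {
                    "parameter": "elastin_pct",
                    "reference": "NN",
                    "comparison": "STH",
                    "percent": relative_difference(e["NN"].mean, e["STH"].mean),
                },
                {
                    "parameter": "elastin_pct",
                    "reference": "STH",
                    "comparison": "LTH",
                    "percent": relative_difference(e["STH"].mean, e["LTH"].mean),
                },
            ]

    report["tables"] = _summaries_to_jsonable(summaries)

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_sidecar_json

        write_sidecar_json(outdir / "report.json", report)
        for param, groups in summaries.items():
            pd.DataFrame(
                [
                    {"group": g, "mean": s.mean, "sem": s.sem, "n": s.n}
                    for g, s in groups.items()
                ]
            ).to_csv(outdir / f"summary_{param}.csv", index=False)
    return report
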