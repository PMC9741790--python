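"""End-to-end experiment orchestration.

Synthesizes (or loads) one recording per subject and walking condition,
segments strides from the vGRF, trims the edge cycles, builds the four
signal forms per channel, runs the SampEn grid over template lengths and
tolerance factors, assembles the long-form sensitivity table, and runs the
per-condition two-way ANOVAs (Type x m) and the velocity-comparison mixed
ANOVA at a fixed template length.

As in the study protocol, the raw-series length and the cycle count entering
the analysis are capped at the lowest value achieved across all subjects and
conditions, so every series is comparable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from gaitent._version import __version__ as _pkg_version
from gaitent.errors import GaitentError, ParameterError
from gaitent.io import read_recording_csv
from gaitent.preprocess import (
    TYPES_BY_VARIABLE,
    ProcessedSignal,
    make_whole,
    normalize_spatial,
    segment_resample,
    zero_cycles,
)
from gaitent.sampen import sampen_grid
from gaitent.segmentation import segment_strides, trim_first_last
from gaitent.stats import AnovaResult, mixed_anova, two_way_anova
from gaitent.synthetic import GaitParams, generate_condition_pair

log = logging.getLogger("gaitent.pipeline")

CONDITIONS = ("Vpref", "Vmax")


def default_vpref_params() -> GaitParams:
    """Preferred-speed condition: 30 s of comfortable treadmill walking."""
    return GaitParams.for_duration(
        30.0,
        mean_stride_time=1.06,
        stride_time_cv=0.02,
        waveform_noise_sd={"copap": 0.2, "copml": 0.1, "vgrf": 4.0},
        within_cycle_shape_jitter={"copap": 0.12, "copml": 0.08, "vgrf": 0.12},
    )


def default_vmax_params() -> GaitParams:
    """Maximum tolerated speed: shorter, slightly more variable strides;
    a tighter fore-aft/vertical pattern but a looser lateral one."""
    return GaitParams.for_duration(
        30.0,
        mean_stride_time=0.85,
        stride_time_cv=0.03,
        waveform_noise_sd={"copap": 0.2, "copml": 0.1, "vgrf": 4.0},
        within_cycle_shape_jitter={"copap": 0.04, "copml": 0.20, "vgrf": 0.04},
    )


@dataclass
class RunConfig:
    """Full experiment configuration.

    ``mode`` is "synthetic" (default) or "files"; in file mode
    ``input_files`` maps subject id -> {condition -> CSV path} and both
    conditions must be present per subject.
    """

    mode: str = "synthetic"
    params_pref: GaitParams = field(default_factory=default_vpref_params)
    params_max: GaitParams = field(default_factory=default_vmax_params)
    n_subjects: int = 23
    m_list: Sequence[int] = (2, 4, 6, 8, 10)
    r_factor_list: Sequence[float] = (0.2,)
    samples_per_cycle: int = 100
    whole_n_points: int = 2200
    variables: Sequence[str] = ("copap", "copml", "vgrf")
    mixed_anova_m: int = 6
    input_files: Mapping[str, Mapping[str, str]] | None = None
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ParameterError("mode", "must be 'synthetic' or 'files'")
        if not self.m_list:
            raise ParameterError("m_list", "must be non-empty")
        bad = set(self.variables) - set(TYPES_BY_VARIABLE)
        if bad:
            raise ParameterError("variables", f"unknown variables {sorted(bad)}")
        if self.mode == "synthetic":
            if self.n_subjects < 1:
                raise ParameterError("n_subjects", "must be >= 1")
            self.params_pref.validate()
            self.params_max.validate()
        else:
            if not self.input_files:
                raise ParameterError("input_files", "required in file mode")
            for subj, paths in self.input_files.items():
                missing = set(CONDITIONS) - set(paths)
                if missing:
                    raise ParameterError(
                        "input_files", f"subject {subj} missing conditions {sorted(missing)}"
                    )


@dataclass
class ExperimentResult:
    """All artifacts of one experiment run."""

    sensitivity: pd.DataFrame
    summary: pd.DataFrame
    velocity_comparison: pd.DataFrame
    anovas: dict[str, dict[str, AnovaResult | None]]
    mixed: dict[str, AnovaResult | None]
    n_points: int
    n_cycles: int
    diagnostics: list[str]
    meta: dict


def _ci95_half_width(values: np.ndarray) -> float:
    n = len(values)
    if n < 2:
        return float("nan")
    return float(t_dist.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n))


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-12s %.2f s", name, t1 - t0)
    return t1


def _gather_recordings(config: RunConfig):
    """Yield (subject_id, condition, trimmed recording, trimmed segmentation)."""
    out = []
    if config.mode == "synthetic":
        rng = np.random.default_rng(config.seed)
        subject_seeds = rng.integers(0, 2**31 - 2, size=config.n_subjects)
        subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
        for subj, sseed in zip(subjects, subject_seeds):
            pair = generate_condition_pair(config.params_pref, config.params_max, int(sseed))
            for cond, rec in zip(CONDITIONS, pair):
                out.append((subj, cond, rec))
    else:
        for subj, paths in sorted(config.input_files.items()):
            for cond in CONDITIONS:
                out.append((subj, cond, read_recording_csv(paths[cond])))
    trimmed = []
    for subj, cond, rec in out:
        try:
            seg = segment_strides(rec)
            rec_t, seg_t = trim_first_last(rec, seg)
        except GaitentError as exc:
            raise GaitentError(f"segmentation stage failed for {subj}/{cond}: {exc}") from exc
        trimmed.append((subj, cond, rec_t, seg_t))
    return trimmed


def _processed_signals(rec, seg, variables, samples_per_cycle, n_points, n_cycles):
    """All (variable, type_tag) -> ProcessedSignal for one recording."""
    signals: dict[tuple[str, str], ProcessedSignal] = {}
    segm: dict[str, ProcessedSignal] = {}
    for var in variables:
        signals[(var, "WHOLE")] = make_whole(rec, var, n_points)
        segm[var] = segment_resample(rec, seg, var, samples_per_cycle, n_cycles)
        signals[(var, "SEGM")] = segm[var]
    for var in variables:
        if var == "vgrf":
            continue
        if "NORM" in TYPES_BY_VARIABLE[var]:
            signals[(var, "NORM")] = normalize_spatial(segm[var])
    if "copap" in segm and "copml" in segm:
        z_ap, z_ml = zero_cycles(segm["copap"], segm["copml"])
        signals[("copap", "ZERO")] = z_ap
        signals[("copml", "ZERO")] = z_ml
    return signals


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Run the full sensitivity + condition-comparison experiment.

    Deterministic given ``config.seed``. Returns the long-form sensitivity
    table, per-condition Type x m mean +/- 0.95 CI summaries, both ANOVA
    families and the velocity-comparison table at ``mixed_anova_m``.
    Subjects with undefined-entropy cells are excluded from the affected
    ANOVA (and logged) to preserve the balanced design.
    """
    config.validate()
    diagnostics: list[str] = []
    t0 = time.perf_counter()

    recordings = _gather_recordings(config)
    t0 = _stage("generate", t0)

    n_points = min(
        config.whole_n_points, min(rec.n_samples for _, _, rec, _ in recordings)
    )
    n_cycles = min(seg.n_strides for _, _, _, seg in recordings)
    if n_points < config.whole_n_points:
        diagnostics.append(
            f"whole_n_points capped at shortest trimmed recording: {n_points}"
        )

    rows = []
    for subj, cond, rec, seg in recordings:
        signals = _processed_signals(
            rec, seg, config.variables, config.samples_per_cycle, n_points, n_cycles
        )
        for (var, tag), sig in signals.items():
            for cell in sampen_grid(sig, config.m_list, config.r_factor_list):
                rows.append(
                    {
                        "subject_id": subj,
                        "condition": cond,
                        "variable": var,
                        "type_tag": tag,
                        "m": cell.m,
                        "r_factor": cell.r_factor,
                        "sampen_value": np.nan if cell.result is None else cell.result.value,
                        "reason": cell.reason or "",
                    }
                )
    table = pd.DataFrame(rows)
    t0 = _stage("sampen", t0)

    r0 = config.r_factor_list[0]
    at_r0 = table[table["r_factor"] == r0]

    summary = (
        at_r0.groupby(["condition", "variable", "type_tag", "m"], observed=True)["sampen_value"]
        .agg(
            mean="mean",
            ci95=lambda v: _ci95_half_width(v.dropna().to_numpy()),
            n="count",
        )
        .reset_index()
    )

    n_subjects_seen = table["subject_id"].nunique()
    anovas: dict[str, dict[str, AnovaResult | None]] = {c: {} for c in CONDITIONS}
    mixed: dict[str, AnovaResult | None] = {}
    if n_subjects_seen < 2:
        diagnostics.append("statistics stage skipped: fewer than 2 subjects")
    else:
        for cond in CONDITIONS:
            for var in config.variables:
                sub = at_r0[(at_r0["condition"] == cond) & (at_r0["variable"] == var)]
                missing = sub.loc[sub["sampen_value"].isna(), "subject_id"].unique()
                if len(missing):
                    diagnostics.append(
                        f"two-way ANOVA {cond}/{var}: excluded subjects "
                        f"{sorted(missing)} (undefined entropy cells)"
                    )
                    sub = sub[~sub["subject_id"].isin(missing)]
                if sub["subject_id"].nunique() < 2 or sub["m"].nunique() < 2:
                    anovas[cond][var] = None
                    diagnostics.append(
                        f"two-way ANOVA {cond}/{var}: skipped, needs >= 2 subjects "
                        "and >= 2 m-levels"
                    )
                    continue
                anovas[cond][var] = two_way_anova(sub)
        for var in config.variables:
            sub = at_r0[(at_r0["variable"] == var) & (at_r0["m"] == config.mixed_anova_m)].copy()
            missing = sub.loc[sub["sampen_value"].isna(), "subject_id"].unique()
            if len(missing):
                diagnostics.append(
                    f"mixed ANOVA {var}: excluded subjects {sorted(missing)}"
                )
                sub = sub[~sub["subject_id"].isin(missing)]
            if sub["subject_id"].nunique() < 2:
                mixed[var] = None
                diagnostics.append(f"mixed ANOVA {var}: skipped, < 2 subjects left")
                continue
            sub["unit_id"] = sub["subject_id"] + "|" + sub["type_tag"]
            mixed[var] = mixed_anova(sub)
        t0 = _stage("anova", t0)

    velocity = (
        at_r0[at_r0["m"] == config.mixed_anova_m]
        .groupby(["variable", "type_tag", "condition"], observed=True)["sampen_value"]
        .agg(
            mean="mean",
            ci95=lambda v: _ci95_half_width(v.dropna().to_numpy()),
            n="count",
        )
        .reset_index()
    )

    meta = {
        "gaitent_version": _pkg_version,
        "seed": config.seed,
        "mode": config.mode,
        "n_subjects": n_subjects_seen,
        "n_points": int(n_points),
        "n_cycles": int(n_cycles),
        "m_list": [int(m) for m in config.m_list],
        "r_factor_list": [float(r) for r in config.r_factor_list],
        "samples_per_cycle": int(config.samples_per_cycle),
        "mixed_anova_m": int(config.mixed_anova_m),
        "params_pref": dataclasses.asdict(config.params_pref),
        "params_max": dataclasses.asdict(config.params_max),
    }

    result = ExperimentResult(
        sensitivity=table,
        summary=summary,
        velocity_comparison=velocity,
        anovas=anovas,
        mixed=mixed,
        n_points=int(n_points),
        n_cycles=int(n_cycles),
        diagnostics=diagnostics,
        meta=meta,
    )
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
        _stage("write", t0)
    for d in diagnostics:
        log.info("diagnostic: %s", d)
    return result


def _write_outputs(result: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.sensitivity.to_csv(out_dir / "sensitivity.csv", index=False, float_format="%.12g")
    result.summary.to_csv(out_dir / "summary.csv", index=False, float_format="%.12g")
    result.velocity_comparison.to_csv(
        out_dir / "velocity_comparison.csv", index=False, float_format="%.12g"
    )
    for cond, per_var in result.anovas.items():
        payload = {
            var: (res.to_dict() if res is not None else None) for var, res in per_var.items()
        }
        (out_dir / f"anova_{cond.lower()}.json").write_text(json.dumps(payload, indent=2))
    (out_dir / "mixed_anova.json").write_text(
        json.dumps(
            {var: (res.to_dict() if res is not None else None) for var, res in result.mixed.items()},
            indent=2,
        )
    )
    meta = dict(result.meta)
    meta["diagnostics"] = result.diagnostics
    (out_dir / "run_meta.json").write_text(json.dumps(meta, indent=2))
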